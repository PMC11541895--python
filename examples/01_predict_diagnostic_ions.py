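"""Predict epoxide precursor and C=C-diagnostic fragment masses.

Epoxidizing a monounsaturated fatty acid adds one oxygen; CID of the
deprotonated epoxide splits the oxirane ring into an aldehyde/alkene
fragment pair 15.9949 Da apart whose masses pinpoint the double bond.
"""

from ccmeldi import diagnostic_pairs_for, display_mz, epoxide_precursor_mz, parse_lipid_name

for name in ["FA 18:1(9Z)", "FA 18:1(10E)", "FA 18:1(10E)[13C5@1-10]", "PG 16:0_18:1(9Z)"]:
    species = parse_lipid_name(name)
    print(f"\n{species.name()}  (epoxide precursor m/z {display_mz(epoxide_precursor_mz(species))})")
    for pair in diagnostic_pairs_for(species):
        print(
            f"  Δ{pair.channel.position}: aldehyde {pair.aldehyde_mz:.4f}"
            f" / alkene {pair.alkene_mz:.4f}"
            f"  (spacing {pair.aldehyde_mz - pair.alkene_mz:.4f} Da)"
        )

# The Δ10 pair of FA 18:1 sits at nominal m/z 185/169; one 13C in the
# retained C1-C10 segment shifts it to 186/170, five to 190/174 — the
# channels used to follow 9Z→10E isomerization with labeled substrates.
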