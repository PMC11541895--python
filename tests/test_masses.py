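"""Mass arithmetic: parsing, compositions, m/z, diagnostic pairs."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracle
from ccmeldi.masses import (
    OXYGEN_MASS,
    AcylChain,
    AmbiguousLabelError,
    DoubleBond,
    ElementalComposition,
    LipidParseError,
    LipidSpecies,
    UnsupportedClassError,
    candidate_channels,
    composition_of,
    diagnostic_pair_mz,
    diagnostic_pairs_for,
    display_mz,
    epoxide_precursor_mz,
    mz_deprotonated,
    parse_lipid_name,
)

CH2 = 14.0156500638


class TestParsing:
    @pytest.mark.parametrize(
        "name, cls, n_chains, sn",
        [
            ("FA 18:1(9Z)", "FA", 1, False),
            ("PG 18:0_16:0", "PG", 2, False),
            ("PG 18:0/16:0", "PG", 2, True),
            ("PC 16:0/18:1(9Z)", "PC", 2, True),
            ("PE 16:0_18:1(11E)", "PE", 2, False),
        ],
    )
    def test_class_chains_sn(self, name, cls, n_chains, sn):
        sp = parse_lipid_name(name)
        assert sp.lipid_class == cls
        assert len(sp.chains) == n_chains
        assert sp.sn_resolved is sn

    def test_bond_annotation(self):
        sp = parse_lipid_name("FA 18:1(9Z)")
        (bond,) = sp.chains[0].double_bonds
        assert (bond.position, bond.geometry) == (9, "Z")
        assert sp.chains[0].n_carbons == 18

    def test_delta_annotation_gives_unknown_geometry(self):
        sp = parse_lipid_name("FA 18:1(Δ9)")
        (bond,) = sp.chains[0].double_bonds
        assert (bond.position, bond.geometry) == (9, "unknown")

    def test_sum_species_has_count_but_no_positions(self):
        sp = parse_lipid_name("FA 18:1")
        assert sp.chains[0].n_double_bonds == 1
        assert sp.chains[0].double_bonds == ()

    @pytest.mark.parametrize(
        "name",
        ["FA 18:1(9Z)", "FA 18:2(9Z,12Z)", "PG 18:0_16:0", "PC 16:0/18:1(9E)",
         "FA 18:1(Δ9)", "FA 18:1(9Z)[13C5@1-10]"],
    )
    def test_round_trip(self, name):
        sp = parse_lipid_name(name)
        assert parse_lipid_name(sp.name()) == sp

    @pytest.mark.parametrize("bad", ["", "FA", "FA x:1", "FA 18:1(99Q)", "PG 18:0", "FA 18:2(9Z)"])
    def test_malformed_raises(self, bad):
        with pytest.raises(LipidParseError):
            parse_lipid_name(bad)

    def test_unsupported_class(self):
        with pytest.raises(UnsupportedClassError):
            parse_lipid_name("SM 34:1")

    def test_isotope_suffix(self):
        sp = parse_lipid_name("FA 18:1(9Z)[2H17]")
        (label,) = sp.chains[0].labels
        assert (label.isotope, label.count, label.positions) == ("2H", 17, None)


class TestComposition:
    @pytest.mark.parametrize(
        "name, formula",
        [("FA 18:1(9Z)", "C18H34O2"), ("FA 18:0", "C18H36O2"), ("FA 16:1(9Z)", "C16H30O2")],
    )
    def test_fa_formula(self, name, formula):
        assert composition_of(parse_lipid_name(name)).formula() == formula

    def test_pg_matches_structural_enumeration(self):
        got = composition_of(parse_lipid_name("PG 18:0/16:0"))
        want = oracle.glycerophospholipid_atoms("PG", (18, 16), ((), ()))
        assert {k: v for k, v in got.counts.items()} == {k: v for k, v in want.items() if v}

    @pytest.mark.parametrize("head", ["PE", "PC"])
    def test_other_heads_match_enumeration(self, head):
        got = composition_of(parse_lipid_name(f"{head} 18:0_16:1(9Z)"))
        want = oracle.glycerophospholipid_atoms(head, (18, 16), ((), (9,)))
        assert dict(got.counts) == {k: v for k, v in want.items() if v}

    def test_labels_preserve_totals(self):
        plain = composition_of(parse_lipid_name("FA 18:1(9Z)"))
        labeled = composition_of(parse_lipid_name("FA 18:1(9Z)[13C5@1-10]"))
        assert labeled.counts["13C"] == 5
        assert labeled.counts["C"] == plain.counts["C"] - 5
        assert sum(labeled.counts.values()) == sum(plain.counts.values())

    def test_invalid_composition_rejected(self):
        with pytest.raises(ValueError):
            ElementalComposition({"C": -1})
        with pytest.raises(ValueError):
            ElementalComposition({"Xx": 2})


class TestMz:
    def test_deprotonated_fa_18_0(self):
        mz = mz_deprotonated(composition_of(parse_lipid_name("FA 18:0")))
        assert mz == pytest.approx(283.2643, abs=1e-4)
        assert display_mz(mz) == 283.26

    def test_deprotonated_fa_18_1(self):
        mz = mz_deprotonated(composition_of(parse_lipid_name("FA 18:1(9Z)")))
        assert mz == pytest.approx(281.2486, abs=1e-4)

    def test_zero_label_variant_identical(self):
        a = composition_of(parse_lipid_name("FA 18:1(9Z)"))
        b = composition_of(
            LipidSpecies("FA", (AcylChain(18, (DoubleBond(9, "Z"),), ()),))
        )
        assert mz_deprotonated(a) == mz_deprotonated(b)

    def test_empty_composition_raises(self):
        with pytest.raises(ValueError):
            mz_deprotonated(ElementalComposition({}))

    @pytest.mark.parametrize(
        "name, shown",
        [("FA 16:1(9Z)", 269.21), ("FA 18:1(9Z)", 297.24),
         ("FA 19:1(9Z)", 311.26), ("FA 20:1(11Z)", 325.27)],
    )
    def test_epoxide_precursors_match_method_table(self, name, shown):
        assert display_mz(epoxide_precursor_mz(parse_lipid_name(name))) == shown

    def test_saturated_species_cannot_be_epoxidized(self):
        with pytest.raises(ValueError, match="double bond"):
            epoxide_precursor_mz(parse_lipid_name("FA 18:0"))

    def test_precursor_independent_of_position_and_geometry(self):
        vals = {
            round(epoxide_precursor_mz(parse_lipid_name(f"FA 18:1({p}{g})")), 6)
            for p in (6, 9, 11)
            for g in ("Z", "E")
        }
        assert len(vals) == 1


class TestDiagnosticPairs:
    def test_delta10_pair(self):
        p = diagnostic_pair_mz(parse_lipid_name("FA 18:1(10E)").channels()[0])
        assert p.aldehyde_mz == pytest.approx(185.1183, abs=1e-4)
        assert p.alkene_mz == pytest.approx(169.1234, abs=1e-4)
        assert (round(p.aldehyde_mz), round(p.alkene_mz)) == (185, 169)

    def test_delta9_pair_matches_structural_oracle(self):
        p = diagnostic_pair_mz(parse_lipid_name("FA 18:1(9Z)").channels()[0])
        assert p.aldehyde_mz == pytest.approx(
            oracle.anion_mz(oracle.aldehyde_fragment_atoms(9, ())), abs=1e-4
        )
        assert p.alkene_mz == pytest.approx(
            oracle.anion_mz(oracle.alkene_fragment_atoms(9, ())), abs=1e-4
        )

    def test_m1_label_shifts_pair_to_186_170(self):
        p = diagnostic_pair_mz(parse_lipid_name("FA 18:1(10E)[13C1@1-9]").channels()[0])
        assert (round(p.aldehyde_mz), round(p.alkene_mz)) == (186, 170)

    def test_13c5_label_in_retained_segment_gives_190(self):
        p = diagnostic_pair_mz(parse_lipid_name("FA 18:1(10E)[13C5@1-10]").channels()[0])
        assert round(p.aldehyde_mz) == 190

    def test_distal_label_leaves_pair_unshifted(self):
        plain = diagnostic_pair_mz(parse_lipid_name("FA 18:1(9Z)").channels()[0])
        distal = diagnostic_pair_mz(parse_lipid_name("FA 18:1(9Z)[2H17@10-18]").channels()[0])
        assert distal.aldehyde_mz == pytest.approx(plain.aldehyde_mz, abs=1e-6)
        assert distal.precursor_mz > plain.precursor_mz

    def test_unpositioned_label_on_cleaved_chain_raises(self):
        ch = parse_lipid_name("FA 18:1(9Z)[13C1]").channels()[0]
        with pytest.raises(AmbiguousLabelError):
            diagnostic_pair_mz(ch)

    def test_straddling_label_raises(self):
        ch = parse_lipid_name("FA 18:1(9Z)[13C2@8-11]").channels()[0]
        with pytest.raises(AmbiguousLabelError):
            diagnostic_pair_mz(ch)

    def test_gpl_pair_below_precursor_with_16da_spacing(self):
        p = diagnostic_pair_mz(parse_lipid_name("PG 16:0_18:1(9Z)").channels()[0])
        assert p.aldehyde_mz < p.precursor_mz
        assert p.aldehyde_mz - p.alkene_mz == pytest.approx(OXYGEN_MASS, abs=1e-4)

    def test_gpl_free_fatty_acid_switch(self):
        sp = parse_lipid_name("PG 16:0_18:1(9Z)")
        released = diagnostic_pair_mz(sp.channels()[0], on_free_fatty_acid=True)
        fa = diagnostic_pair_mz(parse_lipid_name("FA 18:1(9Z)").channels()[0])
        assert released.aldehyde_mz == pytest.approx(fa.aldehyde_mz, abs=1e-9)

    def test_candidate_scan_for_sum_species(self):
        chans = candidate_channels(parse_lipid_name("FA 18:1"))
        assert [c.position for c in chans] == list(range(2, 17))
        with pytest.raises(ValueError, match="monounsaturated"):
            candidate_channels(parse_lipid_name("FA 18:2"))


# -- property tests over the supported FA space ------------------------------

# Δ3..Δn−2 with no adjacent bonds: natural polyunsaturation is methylene-
# interrupted, and a Δ2 channel or cumulated diene has no classical
# terminal-alkene structure for the bond-graph oracle to enumerate
_fa_species = st.integers(14, 22).flatmap(
    lambda n: st.lists(st.integers(3, n - 2), min_size=1, max_size=3, unique=True)
    .map(lambda ps: tuple(sorted(ps)))
    .filter(lambda ps: all(b - a >= 2 for a, b in zip(ps, ps[1:])))
    .map(lambda ps: (n, ps))
)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(_fa_species)
def test_mass_conservation_and_spacing(case):
    """Every channel: aldehyde + lost neutral = precursor; pair split 16 Da."""
    n, positions = case
    sp = LipidSpecies("FA", (AcylChain(n, tuple(DoubleBond(p, "Z") for p in positions)),))
    prec = epoxide_precursor_mz(sp)
    for pair in diagnostic_pairs_for(sp):
        dn = pair.channel.position
        m = n - dn
        d_distal = sum(1 for p in positions if p > dn)
        lost = oracle.monoisotopic({"C": m, "H": 2 * m - 2 * d_distal})
        assert pair.aldehyde_mz + lost == pytest.approx(prec, abs=1e-4)
        assert pair.aldehyde_mz - pair.alkene_mz == pytest.approx(OXYGEN_MASS, abs=1e-4)
        assert pair.aldehyde_mz < prec


@settings(max_examples=150, deadline=None, derandomize=True)
@given(_fa_species)
def test_oracle_equivalence(case):
    """Compositions and all m/z agree with the bond-graph oracle to 1e-4 Th."""
    n, positions = case
    sp = LipidSpecies("FA", (AcylChain(n, tuple(DoubleBond(p, "Z") for p in positions)),))
    assert dict(composition_of(sp).counts) == {
        k: v for k, v in oracle.fatty_acid_atoms(n, positions).items() if v
    }
    assert mz_deprotonated(composition_of(sp)) == pytest.approx(
        oracle.anion_mz(oracle.fatty_acid_atoms(n, positions)), abs=1e-4
    )
    for pair in diagnostic_pairs_for(sp):
        dn = pair.channel.position
        retained = tuple(p for p in positions if p < dn)
        assert pair.precursor_mz == pytest.approx(
            oracle.anion_mz(oracle.epoxide_atoms(n, positions, dn)), abs=1e-4
        )
        assert pair.aldehyde_mz == pytest.approx(
            oracle.anion_mz(oracle.aldehyde_fragment_atoms(dn, retained)), abs=1e-4
        )
        assert pair.alkene_mz == pytest.approx(
            oracle.anion_mz(oracle.alkene_fragment_atoms(dn, retained)), abs=1e-4
        )


@settings(max_examples=60, deadline=None, derandomize=True)
@given(_fa_species, st.data())
def test_geometry_invariance(case, data):
    """Swapping Z↔E on any bond changes no computed m/z."""
    n, positions = case
    geoms = data.draw(
        st.tuples(*[st.sampled_from(["Z", "E"]) for _ in positions]), label="geoms"
    )
    sp_z = LipidSpecies("FA", (AcylChain(n, tuple(DoubleBond(p, "Z") for p in positions)),))
    sp_g = LipidSpecies(
        "FA", (AcylChain(n, tuple(DoubleBond(p, g) for p, g in zip(positions, geoms))),)
    )
    assert epoxide_precursor_mz(sp_z) == epoxide_precursor_mz(sp_g)
    for a, b in zip(diagnostic_pairs_for(sp_z), diagnostic_pairs_for(sp_g)):
        assert a.aldehyde_mz == b.aldehyde_mz
        assert a.alkene_mz == b.alkene_mz


def test_position_monotonicity_one_ch2_per_delta():
    """For a monounsaturated chain the aldehyde climbs one CH2 per Δ unit."""
    prev = None
    for dn in range(2, 17):
        sp = LipidSpecies("FA", (AcylChain(18, (DoubleBond(dn, "Z"),)),))
        mz = diagnostic_pair_mz(sp.channels()[0]).aldehyde_mz
        if prev is not None:
            assert mz - prev == pytest.approx(CH2, abs=1e-4)
        prev = mz
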