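"""Independent brute-force structural oracle for compositions and masses.

Builds each molecule atom by atom from an explicit bond graph — every
carbon's hydrogen count follows from its bond orders — and sums masses
from a second, independent atomic-mass source (pyteomics' NIST table).
Nothing here touches the package's own composition rules.
"""

from collections import Counter

from pyteomics import mass as _pmass

# independent atomic masses (NIST via pyteomics)
M = {sym: _pmass.nist_mass[sym][0][0] for sym in ("C", "H", "O", "N", "P")}
M_PROTON = 1.00727646688


def fatty_acid_atoms(n_carbons: int, bond_positions: tuple[int, ...] = ()) -> Counter:
    """Atom counts of a free fatty acid built from its bond graph.

    Chain C1..Cn; C1 is the carboxyl carbon (one =O, one O-H); a bond at
    Δp makes the C(p)-C(p+1) link double.  Each carbon's H count is
    4 − (sum of bond orders to heavy neighbors).
    """
    double = set(bond_positions)
    atoms = Counter()
    for c in range(1, n_carbons + 1):
        atoms["C"] += 1
        orders = []
        if c > 1:
            orders.append(2 if (c - 1) in double else 1)
        if c < n_carbons:
            orders.append(2 if c in double else 1)
        if c == 1:
            orders.extend([2, 1])  # C=O and C-O(H)
        h = 4 - sum(orders)
        assert h >= 0, f"valence violated at C{c}"
        atoms["H"] += h
    atoms["O"] += 2
    atoms["H"] += 1  # carboxyl O-H
    return atoms


def epoxide_atoms(n_carbons: int, bond_positions: tuple[int, ...], epoxidized: int) -> Counter:
    """Mono-epoxide: the Δ`epoxidized` bond becomes a C-C single bond
    bridged by one oxygen (each ring carbon keeps one substituent H)."""
    assert epoxidized in bond_positions
    remaining = tuple(p for p in bond_positions if p != epoxidized)
    atoms = fatty_acid_atoms(n_carbons, remaining)  # single bond there => +2H
    atoms["O"] += 1  # oxirane oxygen replaces no hydrogens vs the alkane
    atoms["H"] -= 2  # ring carbons bond to O instead of one H each
    return atoms


def aldehyde_fragment_atoms(n_carbons_retained: int, bond_positions: tuple[int, ...]) -> Counter:
    """ω-oxo fatty acid (neutral): chain of the retained carbons with the
    terminal carbon bearing an aldehyde =O; retained C=C stay in place."""
    atoms = fatty_acid_atoms(n_carbons_retained, bond_positions)
    # convert terminal CH3 (or =CH2) end into CHO: replace 2 H by =O
    atoms["O"] += 1
    atoms["H"] -= 2
    return atoms


def alkene_fragment_atoms(n_carbons_retained: int, bond_positions: tuple[int, ...]) -> Counter:
    """Terminal-alkene fatty acid (neutral): aldehyde fragment with the
    C=O replaced by a C=C to the (virtual) next carbon — equivalently the
    fatty acid with an extra terminal unsaturation."""
    return fatty_acid_atoms(
        n_carbons_retained, tuple(bond_positions) + (n_carbons_retained - 1,)
    )


def glycerophospholipid_atoms(
    head: str, chain_carbons: tuple[int, int], chain_bonds: tuple[tuple[int, ...], ...]
) -> Counter:
    """Diacyl glycerophospholipid assembled atom by atom.

    Glycerol backbone: C1H2, C2H1, C3H2 with three oxygens; sn-1/sn-2
    oxygens carry the acyl groups (fatty acid minus its O-H hydrogen and
    with the carboxyl O-H oxygen shared), sn-3 carries the phosphodiester
    to the head group.
    """
    atoms = Counter()
    # glycerol: 3 C, 5 H on carbons, 3 O (all esterified, so no O-H here)
    atoms["C"] += 3
    atoms["H"] += 5
    atoms["O"] += 3
    # two acyl groups: fatty acid minus OH (the ester O comes from glycerol)
    for nc, bonds in zip(chain_carbons, chain_bonds):
        fa = fatty_acid_atoms(nc, bonds)
        fa["O"] -= 1
        fa["H"] -= 1
        atoms += fa
    # phosphate bridging glycerol sn-3 O and the head O: PO2(OH) between them
    atoms["P"] += 1
    atoms["O"] += 3  # two P=O/P-OH oxygens + the head-side bridging O
    atoms["H"] += 1  # the remaining P-O-H
    if head == "PG":
        # head glycerol minus the H of the O that bonds to P:
        # 5 carbon-bound H plus two free hydroxyls
        atoms["C"] += 3
        atoms["H"] += 5
        atoms["O"] += 2
        atoms["H"] += 2
    elif head == "PE":
        # ethanolamine -O-CH2-CH2-NH2 (O bridging counted with phosphate)
        atoms["C"] += 2
        atoms["H"] += 6
        atoms["N"] += 1
    elif head == "PC":
        # choline -O-CH2-CH2-N(CH3)3 (cationic N, no N-H); net neutral
        # zwitterion: the phosphate P-O-H above loses its H to balance
        atoms["C"] += 5
        atoms["H"] += 12
        atoms["N"] += 1
    else:
        raise ValueError(head)
    return atoms


def monoisotopic(atoms: Counter) -> float:
    return sum(M[el] * n for el, n in atoms.items() if n)


def anion_mz(atoms: Counter) -> float:
    """[M−H]⁻ m/z of a neutral built by the oracle."""
    return monoisotopic(atoms) - M_PROTON
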