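"""Exact elemental-composition and monoisotopic m/z arithmetic for lipid epoxides.

Epoxidation of a C=C bond (mCPBA derivatization) adds one oxygen to the
lipid.  Collision-induced dissociation of the deprotonated mono-epoxide
cleaves the oxirane ring and yields two fragments 15.9949 Da apart: an
oxygen-retaining "aldehyde" ion and an oxygen-free "alkene" ion.  Their
masses encode the position of the original double bond, counted from the
carboxyl carbon (Δ-nomenclature: a bond at Δn joins Cn and Cn+1).

All m/z values are negative-mode ([M−H]⁻) monoisotopic values computed
from a fixed internal atomic-mass table; a display helper rounds half-up
to two decimals to match instrument method tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

__all__ = [
    "ATOMIC_MASS",
    "PROTON_MASS",
    "OXYGEN_MASS",
    "CH2_MASS",
    "ElementalComposition",
    "IsotopeLabel",
    "AcylChain",
    "LipidSpecies",
    "EpoxideChannel",
    "DiagnosticPair",
    "LipidParseError",
    "UnsupportedClassError",
    "AmbiguousLabelError",
    "parse_lipid_name",
    "composition_of",
    "mz_deprotonated",
    "epoxide_precursor_mz",
    "diagnostic_pair_mz",
    "diagnostic_pairs_for",
    "candidate_channels",
    "display_mz",
]

# Fixed monoisotopic masses (u).  No external lookup at run time.
ATOMIC_MASS: dict[str, float] = {
    "C": 12.000000,
    "H": 1.0078250319,
    "O": 15.9949146,
    "N": 14.0030740,
    "P": 30.9737615,
    "13C": 13.0033548,
    "2H": 2.0141018,
}

#: Mass of a proton (electron accounted), subtracted for [M−H]⁻.
PROTON_MASS = 1.007276
OXYGEN_MASS = ATOMIC_MASS["O"]
CH2_MASS = ATOMIC_MASS["C"] + 2 * ATOMIC_MASS["H"]
ELECTRON_MASS = 0.00054858

_ISOTOPE_PARENT = {"13C": "C", "2H": "H"}

SUPPORTED_CLASSES = ("FA", "PC", "PE", "PG")


class LipidParseError(ValueError):
    """Raised when a lipid shorthand string cannot be parsed."""


class UnsupportedClassError(LipidParseError):
    """Raised for a syntactically valid but unsupported lipid class."""


class AmbiguousLabelError(ValueError):
    """Raised when an isotope label cannot be partitioned across a cleavage."""


@dataclass(frozen=True)
class ElementalComposition:
    """Element → count map with a formal charge (0 or −1).

    Isotope-tagged counts (keys ``13C``, ``2H``) are *in addition to the
    bookkeeping*: a ``13C`` count displaces a ``C`` count, totals unchanged.
    """

    counts: Mapping[str, int]
    charge: int = 0

    def __post_init__(self) -> None:
        clean = {k: int(v) for k, v in self.counts.items() if v != 0}
        for sym, n in clean.items():
            if sym not in ATOMIC_MASS:
                raise ValueError(f"unknown element symbol {sym!r}")
            if n < 0:
                raise ValueError(f"negative count for {sym}: {n}")
        object.__setattr__(self, "counts", clean)
        if self.charge not in (0, -1):
            raise ValueError("charge must be 0 or -1")

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for k, v in other.counts.items():
            merged[k] = merged.get(k, 0) + v
        return ElementalComposition(merged, self.charge + other.charge)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for k, v in other.counts.items():
            merged[k] = merged.get(k, 0) - v
        return ElementalComposition(merged, self.charge - other.charge)

    def scaled(self, factor: int) -> "ElementalComposition":
        return ElementalComposition({k: v * factor for k, v in self.counts.items()}, self.charge * factor)

    @property
    def monoisotopic_mass(self) -> float:
        if not self.counts:
            raise ValueError("empty composition has no mass")
        return sum(ATOMIC_MASS[sym] * n for sym, n in self.counts.items())

    def formula(self) -> str:
        """Hill-ish formula string, isotopes bracketed (e.g. ``C17[13C]1H33O2``)."""
        order = ["C", "13C", "H", "2H", "N", "O", "P"]
        parts = []
        for sym in order:
            n = self.counts.get(sym, 0)
            if n:
                tag = f"[{sym}]" if sym in _ISOTOPE_PARENT else sym
                parts.append(f"{tag}{n}")
        return "".join(parts)


def comp(charge: int = 0, **elements: int) -> ElementalComposition:
    """Shorthand constructor: ``comp(C=18, H=36, O=2)``."""
    return ElementalComposition(elements, charge)


_WATER = comp(H=2, O=1)
_GLYCEROL = comp(C=3, H=8, O=3)
_PHOSPHORIC = comp(H=3, O=4, P=1)
_HEAD_GROUPS = {
    # head alcohol condensed onto phosphatidic acid (−H2O handled in assembly)
    "PG": _GLYCEROL,
    "PE": comp(C=2, H=7, N=1, O=1),  # ethanolamine
    "PC": comp(C=5, H=13, N=1, O=1),  # choline
}


@dataclass(frozen=True)
class IsotopeLabel:
    """A stable-isotope label on one acyl chain.

    ``positions`` is the set of carbon positions (C1 = carboxyl carbon)
    carrying the label, or ``None`` when unknown.  Unknown positions are
    fine for precursor masses but block fragment partitioning.
    """

    isotope: str  # "13C" or "2H"
    count: int
    positions: frozenset[int] | None = None

    def __post_init__(self) -> None:
        if self.isotope not in _ISOTOPE_PARENT:
            raise ValueError(f"unsupported isotope {self.isotope!r}")
        if self.count < 1:
            raise ValueError("label count must be >= 1")
        if self.positions is not None:
            object.__setattr__(self, "positions", frozenset(self.positions))


@dataclass(frozen=True)
class DoubleBond:
    position: int  # Δn, carboxyl carbon = C1
    geometry: str = "unknown"  # "Z", "E", or "unknown"

    def __post_init__(self) -> None:
        if self.geometry not in ("Z", "E", "unknown"):
            raise ValueError(f"geometry must be Z/E/unknown, got {self.geometry!r}")


@dataclass(frozen=True)
class AcylChain:
    """A fatty-acyl chain: carbon count, C=C bonds, optional isotope labels.

    ``declared_double_bonds`` carries the bond count of sum-composition
    shorthand like ``18:1`` whose positions are not annotated; it must
    match ``double_bonds`` when positions are given.
    """

    n_carbons: int
    double_bonds: tuple[DoubleBond, ...] = ()
    labels: tuple[IsotopeLabel, ...] = ()
    declared_double_bonds: int | None = None

    def __post_init__(self) -> None:
        if self.n_carbons < 2:
            raise ValueError("acyl chain needs >= 2 carbons")
        object.__setattr__(self, "double_bonds", tuple(self.double_bonds))
        object.__setattr__(self, "labels", tuple(self.labels))
        if (
            self.declared_double_bonds is not None
            and self.double_bonds
            and len(self.double_bonds) != self.declared_double_bonds
        ):
            raise ValueError("declared bond count disagrees with annotated bonds")
        positions = [b.position for b in self.double_bonds]
        if positions != sorted(positions) or len(set(positions)) != len(positions):
            raise ValueError("double-bond positions must be strictly increasing")
        for b in self.double_bonds:
            if not 1 <= b.position <= self.n_carbons - 1:
                raise ValueError(
                    f"double-bond position Δ{b.position} outside 1..{self.n_carbons - 1}"
                )
        n_13c = sum(l.count for l in self.labels if l.isotope == "13C")
        if n_13c > self.n_carbons:
            raise ValueError("more 13C labels than carbons")
        for l in self.labels:
            if l.positions is not None:
                if any(not 1 <= p <= self.n_carbons for p in l.positions):
                    raise ValueError("label position outside the chain")
                if l.isotope == "13C" and len(l.positions) < l.count:
                    raise ValueError("13C label has fewer candidate positions than labels")

    @property
    def n_double_bonds(self) -> int:
        if self.double_bonds:
            return len(self.double_bonds)
        return self.declared_double_bonds or 0

    def chain_shorthand(self) -> str:
        s = f"{self.n_carbons}:{self.n_double_bonds}"
        if self.double_bonds and any(b.geometry != "unknown" for b in self.double_bonds):
            ann = ",".join(f"{b.position}{b.geometry}" for b in self.double_bonds)
            s += f"({ann})"
        elif self.double_bonds and all(b.geometry == "unknown" for b in self.double_bonds):
            ann = ",".join(f"Δ{b.position}" for b in self.double_bonds)
            s += f"({ann})"
        for l in self.labels:
            s += f"[{l.isotope}{l.count}"
            if l.positions is not None:
                s += "@" + _format_positions(l.positions)
            s += "]"
        return s


@dataclass(frozen=True)
class LipidSpecies:
    """A fatty acid (one chain) or diacyl glycerophospholipid (two chains)."""

    lipid_class: str
    chains: tuple[AcylChain, ...]
    sn_resolved: bool = False

    def __post_init__(self) -> None:
        if self.lipid_class not in SUPPORTED_CLASSES:
            raise UnsupportedClassError(f"unsupported lipid class {self.lipid_class!r}")
        object.__setattr__(self, "chains", tuple(self.chains))
        want = 1 if self.lipid_class == "FA" else 2
        if len(self.chains) != want:
            raise ValueError(
                f"{self.lipid_class} requires {want} chain(s), got {len(self.chains)}"
            )

    @property
    def n_double_bonds(self) -> int:
        return sum(c.n_double_bonds for c in self.chains)

    def name(self) -> str:
        """Canonical shorthand; parse_lipid_name round-trips through this."""
        if self.lipid_class == "FA":
            return f"FA {self.chains[0].chain_shorthand()}"
        sep = "/" if self.sn_resolved else "_"
        return f"{self.lipid_class} " + sep.join(c.chain_shorthand() for c in self.chains)

    def channels(self) -> list["EpoxideChannel"]:
        """One mono-epoxide channel per C=C bond (di-epoxides not modeled)."""
        out = []
        for ci, chain in enumerate(self.chains):
            for b in chain.double_bonds:
                out.append(EpoxideChannel(self, ci, b.position))
        return out


@dataclass(frozen=True)
class EpoxideChannel:
    """One mono-epoxidized C=C bond of a parent lipid."""

    parent: LipidSpecies
    chain_index: int
    position: int

    def __post_init__(self) -> None:
        chain = self.parent.chains[self.chain_index]
        if self.position not in {b.position for b in chain.double_bonds}:
            raise ValueError(
                f"Δ{self.position} is not a double-bond position of chain {self.chain_index}"
            )


@dataclass(frozen=True)
class DiagnosticPair:
    """Aldehyde/alkene fragment pair for one epoxide channel (Th, [M−H]⁻ scale)."""

    aldehyde_mz: float
    alkene_mz: float
    channel: EpoxideChannel
    precursor_mz: float


# ---------------------------------------------------------------------------
# parsing

_NAME_RE = re.compile(r"^\s*([A-Za-z]+)\s+(.+?)\s*$")
_CHAIN_RE = re.compile(
    r"^(?P<nc>\d+):(?P<nd>\d+)"
    r"(?:\s*\((?P<ann>[^)]*)\))?"
    r"(?P<labels>(?:\s*\[[^\]]*\])*)\s*$"
)
_BOND_RE = re.compile(r"^(?:Δ|d)?(?P<pos>\d+)(?P<geom>[ZE])?$", re.IGNORECASE)
_LABEL_RE = re.compile(
    r"^(?P<iso>13C|2H|D)(?P<count>\d+)?(?:@(?P<pos>[\d,\-]+))?$", re.IGNORECASE
)


def _format_positions(positions: frozenset[int]) -> str:
    """Compress a position set to shorthand runs, e.g. {1,2,3,7} → "1-3,7"."""
    out = []
    run: list[int] = []
    for p in sorted(positions):
        if run and p == run[-1] + 1:
            run.append(p)
        else:
            if run:
                out.append(run)
            run = [p]
    out.append(run)
    return ",".join(f"{r[0]}-{r[-1]}" if len(r) > 1 else str(r[0]) for r in out)


def _parse_positions(text: str) -> frozenset[int]:
    out: set[int] = set()
    for tok in text.split(","):
        if "-" in tok:
            lo, hi = tok.split("-", 1)
            out.update(range(int(lo), int(hi) + 1))
        else:
            out.add(int(tok))
    return frozenset(out)


def _parse_label(token: str) -> IsotopeLabel:
    m = _LABEL_RE.match(token.strip())
    if not m:
        raise LipidParseError(f"malformed isotope label {token!r}")
    iso = m.group("iso").upper()
    iso = {"13C": "13C", "2H": "2H", "D": "2H"}[iso]
    count = int(m.group("count") or 1)
    positions = _parse_positions(m.group("pos")) if m.group("pos") else None
    return IsotopeLabel(iso, count, positions)


def _parse_chain(token: str) -> AcylChain:
    m = _CHAIN_RE.match(token.strip())
    if not m:
        raise LipidParseError(f"malformed chain token {token!r}")
    nc, nd = int(m.group("nc")), int(m.group("nd"))
    bonds: list[DoubleBond] = []
    if m.group("ann"):
        for btok in m.group("ann").split(","):
            bm = _BOND_RE.match(btok.strip())
            if not bm:
                raise LipidParseError(f"malformed double-bond annotation {btok.strip()!r}")
            geom = bm.group("geom")
            bonds.append(DoubleBond(int(bm.group("pos")), geom.upper() if geom else "unknown"))
        if len(bonds) != nd:
            raise LipidParseError(
                f"chain {token.strip()!r}: {nd} bonds declared, {len(bonds)} annotated"
            )
        bonds.sort(key=lambda b: b.position)
    labels = []
    for ltok in re.findall(r"\[([^\]]*)\]", m.group("labels") or ""):
        labels.append(_parse_label(ltok))
    return AcylChain(nc, tuple(bonds), tuple(labels), declared_double_bonds=nd)


def parse_lipid_name(name: str) -> LipidSpecies:
    """Parse Liebisch-style shorthand into a :class:`LipidSpecies`.

    Accepted forms include ``"FA 18:1(9Z)"``, ``"FA 18:1 (Δ9)"``,
    ``"PG 18:0_16:0"`` (sn-position unknown), ``"PC 16:0/18:1(9Z)"``
    (sn-resolved) and isotope suffixes such as ``"FA 18:1(9Z)[13C5@1-10]"``
    or ``"FA 18:1(9Z)[D17]"``.  Bonds without a stated geometry parse as
    geometry ``unknown``.
    """
    m = _NAME_RE.match(name or "")
    if not m:
        raise LipidParseError(f"malformed lipid name {name!r}")
    cls, rest = m.group(1).upper(), m.group(2)
    if cls not in SUPPORTED_CLASSES:
        raise UnsupportedClassError(f"unsupported lipid class {cls!r} in {name!r}")
    if cls == "FA":
        return LipidSpecies("FA", (_parse_chain(rest),))
    sn_resolved = "/" in rest
    sep = "/" if sn_resolved else "_"
    tokens = rest.split(sep)
    if len(tokens) != 2:
        raise LipidParseError(
            f"{cls} needs two chains separated by '_' or '/', got {rest!r}"
        )
    return LipidSpecies(cls, tuple(_parse_chain(t) for t in tokens), sn_resolved)


# ---------------------------------------------------------------------------
# composition and m/z

def _chain_residue_composition(chain: AcylChain) -> ElementalComposition:
    # free fatty acid CnH(2n-2d)O2
    c = comp(C=chain.n_carbons, H=2 * chain.n_carbons - 2 * chain.n_double_bonds, O=2)
    return _apply_labels(c, chain.labels)


def _apply_labels(c: ElementalComposition, labels: Iterable[IsotopeLabel]) -> ElementalComposition:
    counts = dict(c.counts)
    for l in labels:
        parent = _ISOTOPE_PARENT[l.isotope]
        if counts.get(parent, 0) < l.count:
            raise ValueError(f"label {l.isotope}x{l.count} exceeds available {parent}")
        counts[parent] -= l.count
        counts[l.isotope] = counts.get(l.isotope, 0) + l.count
    return ElementalComposition(counts, c.charge)


def composition_of(species: LipidSpecies) -> ElementalComposition:
    """Neutral elemental composition of the (underivatized) lipid.

    FA: CnH(2n−2d)O2.  Diacyl glycerophospholipids are assembled as
    glycerol-3-phosphate + head-group alcohol + two fatty acids with one
    water lost per ester/phosphoester condensation.
    """
    if species.lipid_class == "FA":
        return _chain_residue_composition(species.chains[0])
    g3p = _GLYCEROL + _PHOSPHORIC - _WATER
    total = g3p + _HEAD_GROUPS[species.lipid_class] - _WATER
    for chain in species.chains:
        total = total + _chain_residue_composition(chain) - _WATER
    return total


def mz_deprotonated(composition: ElementalComposition) -> float:
    """m/z of the [M−H]⁻ anion: neutral monoisotopic mass − 1.007276."""
    return composition.monoisotopic_mass - PROTON_MASS


def _anion_mz(species: LipidSpecies) -> float:
    c = composition_of(species)
    if species.lipid_class == "PC":
        # PC carries a fixed positive charge on choline; in negative mode we
        # model the demethylated [M−CH3]⁻ anion.  Experimental: the acetate
        # adduct route is not modeled.
        return c.monoisotopic_mass - (ATOMIC_MASS["C"] + 3 * ATOMIC_MASS["H"]) + ELECTRON_MASS
    return mz_deprotonated(c)


def epoxide_precursor_mz(species: LipidSpecies) -> float:
    """m/z of the deprotonated mono-epoxide: anion m/z + one oxygen.

    Independent of which C=C bond carries the epoxide and of geometry.
    """
    if species.n_double_bonds < 1:
        raise ValueError(f"{species.name()} has no double bond to epoxidize")
    return _anion_mz(species) + OXYGEN_MASS


def _lost_neutral_composition(channel: EpoxideChannel) -> ElementalComposition:
    """Neutral alkene lost on cleavage at the epoxide: the chain segment
    distal to the cleaved bond, C_m H_(2m−2d') with m = n_carbons − Δn and
    d' = number of other C=C bonds entirely within the lost segment."""
    chain = channel.parent.chains[channel.chain_index]
    dn = channel.position
    m_c = chain.n_carbons - dn
    d_distal = sum(1 for b in chain.double_bonds if b.position > dn)
    lost = comp(C=m_c, H=2 * m_c - 2 * d_distal)
    # isotope labels sitting in the lost segment leave with it
    lost_labels = []
    for l in chain.labels:
        if l.positions is None:
            raise AmbiguousLabelError(
                f"label {l.isotope}x{l.count} on the cleaved chain has no stated "
                f"positions; cannot partition across the Δ{dn} cleavage — "
                "provide explicit label positions"
            )
        # the position set bounds where the labels sit; the whole label must
        # fall on one side of the cleavage to partition unambiguously
        if all(p <= dn for p in l.positions):
            continue  # retained with the charged fragment
        if all(p > dn for p in l.positions):
            lost_labels.append(IsotopeLabel(l.isotope, l.count))
        else:
            raise AmbiguousLabelError(
                f"label {l.isotope}x{l.count} position set straddles the Δ{dn} "
                "cleavage; provide positions confined to one side"
            )
    return _apply_labels(lost, lost_labels)


def diagnostic_pair_mz(channel: EpoxideChannel, on_free_fatty_acid: bool = False) -> DiagnosticPair:
    """Aldehyde/alkene diagnostic fragment pair for one epoxide channel.

    The aldehyde ion is the precursor minus the neutral alkene distal to
    the epoxidized bond; the alkene ion is the aldehyde minus one oxygen.
    Geometry never enters.  For glycerophospholipids the neutral loss is
    applied to the intact deprotonated epoxide (charge retained on the
    head-group side); ``on_free_fatty_acid=True`` instead computes the
    pair on the released epoxy-fatty-acylate.
    """
    species = channel.parent
    if on_free_fatty_acid and species.lipid_class != "FA":
        fa = LipidSpecies("FA", (species.chains[channel.chain_index],))
        inner = diagnostic_pair_mz(EpoxideChannel(fa, 0, channel.position))
        return DiagnosticPair(inner.aldehyde_mz, inner.alkene_mz, channel,
                              epoxide_precursor_mz(species))
    precursor = epoxide_precursor_mz(species)
    lost = _lost_neutral_composition(channel).monoisotopic_mass
    aldehyde = precursor - lost
    return DiagnosticPair(aldehyde, aldehyde - OXYGEN_MASS, channel, precursor)


def diagnostic_pairs_for(species: LipidSpecies, **kw) -> list[DiagnosticPair]:
    """All mono-epoxide diagnostic pairs of a species, one per C=C bond."""
    return [diagnostic_pair_mz(ch, **kw) for ch in species.channels()]


def candidate_channels(
    species: LipidSpecies, positions: Iterable[int] | None = None
) -> list[EpoxideChannel]:
    """Epoxide channels to query for a species, enumerating unknown positions.

    With annotated bond positions this is just :meth:`LipidSpecies.channels`.
    For a monounsaturated sum species (e.g. ``"FA 18:1"``) every candidate
    Δ in ``positions`` (default Δ2..Δn−2) gets a channel, so the targeted
    search can read the true position off whichever diagnostic pair shows
    peaks.  Unannotated polyunsaturated species are refused: their channel
    enumeration is combinatorial and needs explicit positions.
    """
    if species.channels():
        return species.channels()
    chain = species.chains[0]
    if species.lipid_class != "FA" or chain.n_double_bonds != 1:
        raise ValueError(
            f"{species.name()}: candidate-position scan supports only "
            "monounsaturated FA; annotate bond positions explicitly"
        )
    cand = list(positions) if positions is not None else range(2, chain.n_carbons - 1)
    out = []
    for p in cand:
        variant = LipidSpecies(
            "FA",
            (AcylChain(chain.n_carbons, (DoubleBond(p),), chain.labels),),
        )
        out.append(EpoxideChannel(variant, 0, p))
    return out


def display_mz(mz: float, ndigits: int = 2) -> float:
    """User-facing rounding, half-up (instrument tables print 283.26 etc.)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(mz)).quantize(q, rounding=ROUND_HALF_UP))
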