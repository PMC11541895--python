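"""Isomer fractions, cis/trans calibration, and isotope-tracer statistics.

The fractional composition of the C=C isomers of one lipid species is
the summed diagnostic-pair EIC area of each isomer divided by the summed
pair area over all isomers of that species — a ratio measure that is
scale-invariant and, with equal per-isomer response factors, directly
estimates the molar composition (calibration slope ≈ 1).

Tracer enrichment uses per-channel areas of the labeled and unlabeled
diagnostic ions, e.g. the M+1 fragment fraction
(A170 + A186) / (A169 + A185 + A170 + A186), and abundances normalized
to a co-spiked deuterated internal standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .annotation import InsufficientDataError, IsomerAssignment

__all__ = [
    "IsomerProfile",
    "CalibrationFit",
    "TracerTimePoint",
    "UndefinedFractionError",
    "NormalizationError",
    "isomer_fractions",
    "fit_calibration",
    "m_plus_fraction",
    "tracer_quant",
]


class UndefinedFractionError(ZeroDivisionError):
    """All contributing areas are zero; the fraction is undefined."""


class NormalizationError(ValueError):
    """Internal-standard area missing or zero."""


@dataclass
class IsomerProfile:
    """Normalized C=C isomer composition of one lipid sum species."""

    species_name: str
    entries: list[dict]  # position, geometry, area, fraction
    total_area: float

    def fraction(self, position: int, geometry: str) -> float:
        for e in self.entries:
            if e["position"] == position and e["geometry"] == geometry:
                return e["fraction"]
        raise KeyError(f"no entry for Δ{position}{geometry}")


@dataclass(frozen=True)
class CalibrationFit:
    """OLS fit of measured area fraction (%) vs molar E fraction (%)."""

    slope: float
    intercept: float
    r2: float
    n_levels: int
    n_replicates: int


@dataclass
class TracerTimePoint:
    """Tracer readout at one incubation time."""

    time_h: float
    unlabeled_areas: tuple[float, float]  # (alkene, aldehyde) e.g. A169, A185
    labeled_areas: tuple[float, float]  # (alkene, aldehyde) e.g. A170, A186
    istd_area: float
    m1_fraction: float = field(init=False)
    normalized_labeled: float = field(init=False)
    normalized_unlabeled: float = field(init=False)

    def __post_init__(self) -> None:
        a_u = sum(self.unlabeled_areas)
        a_l = sum(self.labeled_areas)
        try:
            self.m1_fraction = m_plus_fraction(
                self.unlabeled_areas[0], self.unlabeled_areas[1],
                self.labeled_areas[0], self.labeled_areas[1],
            )
        except UndefinedFractionError:
            self.m1_fraction = float("nan")  # nothing detected at this time
        if self.istd_area <= 0:
            raise NormalizationError(
                f"t={self.time_h} h: internal-standard area is {self.istd_area}"
            )
        self.normalized_labeled = a_l / self.istd_area
        self.normalized_unlabeled = a_u / self.istd_area


def isomer_fractions(
    assignments: Sequence[IsomerAssignment],
    aldehyde_only: bool = False,
    response_factors: Mapping[tuple[int, str], float] | None = None,
) -> IsomerProfile:
    """Fractional C=C isomer composition from annotated pair areas.

    Per isomer the aldehyde and alkene areas are summed (``aldehyde_only``
    restricts to the aldehyde channel), optionally divided by a per-isomer
    response factor, then normalized to the per-species total.  A zero
    total yields NaN fractions, reported as such rather than raised.
    """
    if not assignments:
        raise ValueError("no assignments to profile")
    names = {a.species.name() for a in assignments}
    if len(names) > 1:
        raise ValueError(f"assignments span multiple species: {sorted(names)}")
    entries = []
    for a in assignments:
        area = a.aldehyde_area if aldehyde_only else a.pair_area
        if response_factors:
            area /= response_factors.get((a.position, a.geometry), 1.0)
        entries.append({"position": a.position, "geometry": a.geometry, "area": area})
    total = sum(e["area"] for e in entries)
    for e in entries:
        e["fraction"] = e["area"] / total if total > 0 else float("nan")
    entries.sort(key=lambda e: (e["position"], e["geometry"]))
    return IsomerProfile(names.pop(), entries, total)


def fit_calibration(
    mixtures: Sequence[tuple[float, Sequence[float]]],
    average_replicates: bool = True,
) -> CalibrationFit:
    """Fit the cis/trans calibration line from mixture measurements.

    ``mixtures`` holds (molar E fraction %, replicate measured area
    fractions %) per level; replicates are averaged before the OLS fit
    unless ``average_replicates`` is False, in which case every replicate
    enters as its own point.
    """
    if len(mixtures) < 3:
        raise InsufficientDataError(
            f"calibration needs >= 3 mixture levels, got {len(mixtures)}"
        )
    xs, ys = [], []
    n_rep = 0
    for molar, reps in mixtures:
        reps = list(reps)
        if not reps:
            raise ValueError(f"level {molar}% has no replicate measurements")
        n_rep = max(n_rep, len(reps))
        if average_replicates:
            xs.append(molar)
            ys.append(float(np.mean(reps)))
        else:
            xs.extend([molar] * len(reps))
            ys.extend(reps)
    res = stats.linregress(xs, ys)
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n_levels=len(mixtures),
        n_replicates=n_rep,
    )


def m_plus_fraction(
    unlabeled_alkene: float,
    unlabeled_aldehyde: float,
    labeled_alkene: float,
    labeled_aldehyde: float,
) -> float:
    """Labeled-over-total fraction of diagnostic-ion areas.

    For the M+1 channels of FA 18:1 Δ10 this is
    (A170 + A186) / (A169 + A185 + A170 + A186); the same formula serves
    any label shift (e.g. the M+5 channels at m/z 190/174).  No natural
    isotope-abundance correction is applied.
    """
    areas = (unlabeled_alkene, unlabeled_aldehyde, labeled_alkene, labeled_aldehyde)
    if any(a < 0 for a in areas):
        raise ValueError("areas must be non-negative")
    total = sum(areas)
    if total == 0:
        raise UndefinedFractionError("all four diagnostic areas are zero")
    return (labeled_alkene + labeled_aldehyde) / total


def tracer_quant(
    timepoints: Sequence[Mapping[str, float]],
) -> list[TracerTimePoint]:
    """Assemble a tracer time course from per-timepoint diagnostic areas.

    Each mapping needs keys ``time_h``, ``unlabeled_alkene``,
    ``unlabeled_aldehyde``, ``labeled_alkene``, ``labeled_aldehyde`` and
    ``istd_area``.  Time points are kept in input order; a missing or
    zero internal standard raises per time point.
    """
    out = []
    for tp in timepoints:
        out.append(
            TracerTimePoint(
                time_h=float(tp["time_h"]),
                unlabeled_areas=(float(tp["unlabeled_alkene"]), float(tp["unlabeled_aldehyde"])),
                labeled_areas=(float(tp["labeled_alkene"]), float(tp["labeled_aldehyde"])),
                istd_area=float(tp["istd_area"]),
            )
        )
    return out
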