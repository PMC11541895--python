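"""C=C position and cis/trans geometry assignment.

Position comes for free from diagnostic-pair identity (each Δ has its own
fragment masses).  Geometry is not mass-encoded; it is read from
reversed-phase retention behavior: within a positional-isomer series of
fixed chain length and geometry, apex RT falls linearly with Δ, and at a
given Δ the trans (E) epoxide elutes after the cis (Z) epoxide.  Fitting
that linear RT index on standards allows standard-free assignment of
unknowns; with no model, elution order alone is trusted only for exactly
two co-detected isomers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .chromatograms import (
    ChannelNotFoundError,
    PairEvent,
    TargetedRun,
    detect_peaks,
    extract_eic,
    match_pair_coelution,
)
from .masses import (
    LipidSpecies,
    candidate_channels,
    diagnostic_pair_mz,
    parse_lipid_name,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SeriesKey",
    "RTIndexModel",
    "IsomerAssignment",
    "InsufficientDataError",
    "fit_rt_index",
    "predict_position",
    "call_geometry",
    "annotate_run",
    "integrate_pair",
]

#: integer-snap residual above this fraction of |slope| flags an assignment
AMBIGUITY_FRACTION = 0.4
#: RT models are not extrapolated more than this many Δ units past the fit
MAX_EXTRAPOLATION = 3


class InsufficientDataError(ValueError):
    """Too few points to fit the requested model."""


@dataclass(frozen=True)
class SeriesKey:
    """Identifies one RT-index series: isomers differing only in Δ."""

    lipid_class: str
    n_carbons: int
    n_double_bonds: int
    geometry: str  # "Z" or "E"


@dataclass(frozen=True)
class RTIndexModel:
    """Linear retention-time index RT = slope·Δ + intercept for one series."""

    key: SeriesKey
    slope: float  # min per Δ unit; negative in reversed phase
    intercept: float  # min
    r2: float
    n_points: int
    delta_range: tuple[int, int]

    def predict_rt(self, position: float) -> float:
        return self.slope * position + self.intercept

    def extrapolated(self, position: float) -> bool:
        lo, hi = self.delta_range
        return position < lo - MAX_EXTRAPOLATION or position > hi + MAX_EXTRAPOLATION


@dataclass
class IsomerAssignment:
    """One annotated C=C isomer: species, Δ, geometry, RT, pair areas."""

    species: LipidSpecies
    position: int
    geometry: str  # "Z", "E", or "unknown"
    apex_rt: float
    aldehyde_area: float
    alkene_area: float
    flags: list[str] = field(default_factory=list)
    rt_residual: float | None = None

    @property
    def pair_area(self) -> float:
        return self.aldehyde_area + self.alkene_area


def fit_rt_index(
    standards: Sequence[tuple[int, str, float]],
    key: SeriesKey | None = None,
) -> dict[str, RTIndexModel]:
    """Fit per-geometry linear RT indices from (Δ, geometry, apex_rt) standards.

    Ordinary least squares per geometry series; a geometry needs at least
    two distinct Δ values.  Returns ``{"Z": model, "E": model}`` with only
    the geometries that could be fitted; raises if none could.
    """
    models: dict[str, RTIndexModel] = {}
    for geom in ("Z", "E"):
        pts = [(d, rt) for d, g, rt in standards if g == geom]
        if not pts:
            continue
        deltas = np.array([p[0] for p in pts], dtype=float)
        rts = np.array([p[1] for p in pts], dtype=float)
        if len(set(deltas)) < 2:
            raise InsufficientDataError(
                f"geometry {geom}: need >= 2 distinct Δ values, got {sorted(set(deltas))}"
            )
        res = stats.linregress(deltas, rts)
        k = key or SeriesKey("FA", 0, 0, geom)
        models[geom] = RTIndexModel(
            key=SeriesKey(k.lipid_class, k.n_carbons, k.n_double_bonds, geom),
            slope=float(res.slope),
            intercept=float(res.intercept),
            r2=float(res.rvalue**2),
            n_points=len(pts),
            delta_range=(int(deltas.min()), int(deltas.max())),
        )
    if not models:
        raise InsufficientDataError("no standards provided for either geometry")
    return models


def predict_position(model: RTIndexModel, apex_rt: float) -> tuple[float, int, float, bool]:
    """Invert the RT index: RT → (Δ real, Δ snapped, residual min, ambiguous).

    The residual is |apex_rt − predicted RT at the snapped Δ|; a residual
    beyond 40% of |slope| means the point sits near the midline between
    two adjacent positions and the snap is flagged ambiguous.
    """
    if model.slope == 0:
        raise ValueError("degenerate RT model with zero slope")
    real = (apex_rt - model.intercept) / model.slope
    snapped = int(round(real))
    residual = abs(apex_rt - model.predict_rt(snapped))
    ambiguous = residual > AMBIGUITY_FRACTION * abs(model.slope)
    return real, snapped, residual, ambiguous


def call_geometry(
    events: Sequence[PairEvent],
    position: int,
    models: Mapping[str, RTIndexModel] | None = None,
    rt_threshold: float | None = None,
) -> list[str]:
    """Label co-channel events at one Δ as Z/E/unknown.

    Exactly two events: elution order decides (cis before trans).  One
    event: unknown, unless an RT model places it on the Z or E line within
    ``rt_threshold`` (default 40% of |slope|).  More than two events:
    nearest model line only — raw order is never trusted there.
    """
    events = sorted(events, key=lambda e: e.apex_rt)
    if not events:
        return []

    def _by_model(e: PairEvent) -> str:
        if not models:
            return "unknown"
        best, best_d = "unknown", float("inf")
        for geom, m in models.items():
            if m.extrapolated(position):
                continue
            d = abs(e.apex_rt - m.predict_rt(position))
            thr = rt_threshold if rt_threshold is not None else AMBIGUITY_FRACTION * abs(m.slope)
            if d <= thr and d < best_d:
                best, best_d = geom, d
        return best

    if len(events) == 2 and not models:
        return ["Z", "E"]
    if len(events) == 2 and models:
        labels = [_by_model(e) for e in events]
        if labels == ["unknown", "unknown"]:
            return ["Z", "E"]
        return labels
    return [_by_model(e) for e in events]


def annotate_run(
    run: TargetedRun,
    targets: Sequence[str | LipidSpecies],
    models: Mapping[str, RTIndexModel] | Mapping[SeriesKey, RTIndexModel] | None = None,
    ms2_tol: float = 0.3,
    rt_tol: float = 0.1,
    peak_params: dict | None = None,
) -> list[IsomerAssignment]:
    """Full targeted annotation: EIC → peaks → pair matching → Δ/geometry.

    For every target species and every mono-epoxide channel, the aldehyde
    and alkene fragment EICs are extracted from the species' MS2 channel,
    peaks detected, co-eluting pairs matched, the position read off the
    pair identity, and geometry called from elution order / RT models.
    Every assignment carries its pair areas for downstream quantification.
    """
    peak_params = peak_params or {}
    assignments: list[IsomerAssignment] = []
    for target in targets:
        species = parse_lipid_name(target) if isinstance(target, str) else target
        series_models = _models_for(models, species)
        pairs = [diagnostic_pair_mz(ch) for ch in candidate_channels(species)]
        for pair in pairs:
            try:
                ald = extract_eic(run, 2, pair.precursor_mz, pair.aldehyde_mz, ms2_tol)
                alk = extract_eic(run, 2, pair.precursor_mz, pair.alkene_mz, ms2_tol)
            except ChannelNotFoundError:
                raise
            matching = match_pair_coelution(
                detect_peaks(ald, **peak_params), detect_peaks(alk, **peak_params), rt_tol
            )
            events = matching.events
            geoms = call_geometry(events, pair.channel.position, series_models)
            for ev, geom in zip(sorted(events, key=lambda e: e.apex_rt), geoms):
                flags = []
                residual = None
                if series_models and geom in series_models:
                    m = series_models[geom]
                    _, _, residual, amb = predict_position(m, ev.apex_rt)
                    if amb:
                        flags.append("rt_residual_high")
                assignments.append(
                    IsomerAssignment(
                        species=species,
                        position=pair.channel.position,
                        geometry=geom,
                        apex_rt=ev.apex_rt,
                        aldehyde_area=ev.aldehyde.area,
                        alkene_area=ev.alkene.area,
                        flags=flags,
                        rt_residual=residual,
                    )
                )
            for p in matching.singleton_aldehydes + matching.singleton_alkenes:
                logger.info(
                    "singleton fragment peak at %.2f min (Δ%d, %s) excluded",
                    p.apex_rt, pair.channel.position, species.name(),
                )
    assignments.sort(key=lambda a: (a.species.name(), a.position, a.apex_rt))
    return assignments


def integrate_pair(
    run: TargetedRun,
    pair,
    ms2_tol: float = 0.3,
    rt_tol: float = 0.1,
    expected_rt: float | None = None,
    peak_params: dict | None = None,
) -> float:
    """Summed pair area of one co-eluting aldehyde/alkene event.

    Extracts both fragment EICs of a :class:`~ccmeldi.masses.DiagnosticPair`
    from its MS2 channel, detects peaks, matches the pair and returns the
    summed area of the matched event nearest ``expected_rt`` (largest
    event if no RT is given); 0.0 when nothing co-elutes.
    """
    peak_params = peak_params or {}
    ald = extract_eic(run, 2, pair.precursor_mz, pair.aldehyde_mz, ms2_tol)
    alk = extract_eic(run, 2, pair.precursor_mz, pair.alkene_mz, ms2_tol)
    matching = match_pair_coelution(
        detect_peaks(ald, **peak_params), detect_peaks(alk, **peak_params), rt_tol
    )
    if not matching.events:
        return 0.0
    if expected_rt is not None:
        best = min(matching.events, key=lambda e: abs(e.apex_rt - expected_rt))
    else:
        best = max(matching.events, key=lambda e: e.pair_area)
    return best.pair_area


def _models_for(models, species: LipidSpecies) -> dict[str, RTIndexModel] | None:
    """Accept either {"Z": model, "E": model} or {SeriesKey: model} maps."""
    if not models:
        return None
    sample_key = next(iter(models))
    if isinstance(sample_key, str):
        return dict(models)
    chain = species.chains[0]
    out = {}
    for key, m in models.items():
        if (
            key.lipid_class == species.lipid_class
            and key.n_carbons == chain.n_carbons
            and key.n_double_bonds == chain.n_double_bonds
        ):
            out[key.geometry] = m
    return out or None
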