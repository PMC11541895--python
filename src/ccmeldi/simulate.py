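"""Synthetic targeted-run generator with exact ground truth.

Emulates the acquisition used for epoxidized-lipid C=C analysis: a full
MS1 scan interleaved with a handful of targeted CID MS2 events, Gaussian
chromatographic peaks whose apex times follow a linear position→RT law
(RT = slope·Δ + intercept, plus a fixed late shift for trans isomers),
diagnostic-ion pairs at exactly computed m/z, configurable molar
fractions and response factors, and simple noise (multiplicative
log-normal on peak amplitude, Poisson baseline, ppm-scale m/z jitter).

Defaults mirror the reference chromatography: slope −0.30 min per Δ
unit, trans offset +0.6 min, peak σ = 3 s, isolation width 2.0 Th.  All
randomness flows from one recorded seed; identical specs give
byte-identical mzML output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chromatograms import Scan, TargetedRun
from .masses import (
    DiagnosticPair,
    diagnostic_pair_mz,
    epoxide_precursor_mz,
    parse_lipid_name,
)

__all__ = [
    "SimIsomer",
    "SimSpec",
    "simulate_run",
    "simulate_calibration_series",
    "calibration_mixtures",
    "simulate_tracer_timecourse",
    "DEFAULT_STANDARD_PANEL",
]


@dataclass(frozen=True)
class SimIsomer:
    """One C=C isomer in the simulated panel."""

    position: int
    geometry: str  # "Z" or "E"
    molar_fraction: float
    response_factor: float = 1.0
    label: str | None = None  # isotope suffix, e.g. "13C1@1-9" or "2H17@10-18"
    rt_shift: float = 0.0  # extra apex shift (min) on top of the RT law

    def species_name(self, base: str, with_label: bool = True) -> str:
        cls, rest = base.split(" ", 1)
        if "[" in rest:  # species-level isotope suffix stays after the bond
            core, suffix = rest.split("[", 1)
            suffix = "[" + suffix
        else:
            core, suffix = rest, ""
        name = f"{cls} {core.strip()}({self.position}{self.geometry}){suffix}"
        if self.label and with_label:
            name += f"[{self.label}]"
        return name


@dataclass
class SimSpec:
    """Full description of one simulated targeted run.

    ``panel`` maps a sum-composition species name (e.g. ``"FA 18:1"``)
    to its isomers; molar fractions must sum to 1 per species.
    ``species_amount`` scales the total injected pair area (counts·min)
    per species.
    """

    panel: dict[str, list[SimIsomer]]
    rt_slope: float = -0.30  # min per Δ unit
    rt_intercept: float = 18.0  # min; places Δ9 mid-gradient
    trans_offset: float = 0.6  # min; E elutes after Z
    sigma_s: float = 3.0  # Gaussian peak σ, seconds
    rt_start: float = 12.0
    rt_end: float = 19.0
    ms1_interval_s: float = 2.4
    ms2_interval_s: float = 2.4
    isolation_width: float = 2.0  # Th
    underivatized_offset_min: float = 1.5  # residual parent elutes this much later
    species_amount: dict[str, float] = field(default_factory=dict)
    default_amount: float = 1.0e6  # counts·min of summed pair area per species
    pair_split: tuple[float, float] = (0.6, 0.4)  # aldehyde : alkene
    noise_cv: float = 0.0  # log-normal sd on peak amplitude
    baseline: float = 0.0  # Poisson baseline mean, counts per point
    rt_jitter_min: float = 0.0
    mz_jitter_ppm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_s <= 0 or self.ms1_interval_s <= 0 or self.ms2_interval_s <= 0:
            raise ValueError("σ and scan intervals must be positive")
        for name, isomers in self.panel.items():
            tot = sum(i.molar_fraction for i in isomers)
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(
                    f"{name}: molar fractions sum to {tot}, expected 1"
                )

    @property
    def sigma_min(self) -> float:
        return self.sigma_s / 60.0


@dataclass(frozen=True)
class _Injected:
    species_name: str
    full_name: str
    position: int
    geometry: str
    label: str | None
    pair: DiagnosticPair
    apex_rt: float
    area: float  # realized summed pair area (after amplitude noise)
    area_nominal: float
    fraction: float
    channel_center: float


def _apex_rt(spec: SimSpec, iso: SimIsomer, rng: np.random.Generator) -> float:
    rt = spec.rt_slope * iso.position + spec.rt_intercept + iso.rt_shift
    if iso.geometry == "E":
        rt += spec.trans_offset
    if spec.rt_jitter_min > 0:
        rt += rng.normal(0.0, spec.rt_jitter_min)
    return rt


def simulate_run(spec: SimSpec) -> tuple[TargetedRun, pd.DataFrame]:
    """Generate one targeted run and its ground-truth table.

    Isomers whose (possibly isotope-shifted) epoxide precursor falls
    inside the base species' isolation window share that MS2 channel,
    emulating co-isolation of M and M+n species; otherwise they get
    their own channel.  MS1 scans carry every epoxide precursor peak.
    """
    rng = np.random.default_rng(spec.seed)
    run = TargetedRun(metadata={"seed": spec.seed, "polarity": "negative"})
    injected: list[_Injected] = []

    for sp_name, isomers in spec.panel.items():
        # isolation center targets the species-level (per-isomer-label-free)
        # epoxide precursor; labeled variants co-isolate within the window
        base = parse_lipid_name(isomers[0].species_name(sp_name, with_label=False))
        base_center = epoxide_precursor_mz(base)
        amount = spec.species_amount.get(sp_name, spec.default_amount)
        for iso in isomers:
            species = parse_lipid_name(iso.species_name(sp_name))
            pair = diagnostic_pair_mz(
                next(c for c in species.channels() if c.position == iso.position)
            )
            center = (
                base_center
                if abs(pair.precursor_mz - base_center) <= spec.isolation_width / 2.0
                else pair.precursor_mz
            )
            run.get_or_create_channel(center, spec.isolation_width)
            nominal = amount * iso.molar_fraction * iso.response_factor
            realized = nominal * (
                math.exp(rng.normal(0.0, spec.noise_cv)) if spec.noise_cv > 0 else 1.0
            )
            injected.append(
                _Injected(
                    species_name=sp_name,
                    full_name=species.name(),
                    position=iso.position,
                    geometry=iso.geometry,
                    label=iso.label,
                    pair=pair,
                    apex_rt=_apex_rt(spec, iso, rng),
                    area=realized,
                    area_nominal=nominal,
                    fraction=iso.molar_fraction,
                    channel_center=center,
                )
            )

    sig = spec.sigma_min
    norm = 1.0 / (sig * math.sqrt(2.0 * math.pi))

    def _jitter_mz(mz: np.ndarray) -> np.ndarray:
        if spec.mz_jitter_ppm > 0:
            return mz * (1.0 + rng.normal(0.0, spec.mz_jitter_ppm * 1e-6, size=mz.shape))
        return mz

    # MS1: every epoxide precursor as a Gaussian at the isomer apex
    ms1_times = np.arange(spec.rt_start, spec.rt_end, spec.ms1_interval_s / 60.0)
    # epoxide precursors, plus residual underivatized parents ([M−H]⁻, one
    # oxygen lighter) eluting later: epoxidation reduces hydrophobicity
    from .masses import OXYGEN_MASS

    prec_mz = np.array(
        [inj.pair.precursor_mz for inj in injected]
        + [inj.pair.precursor_mz - OXYGEN_MASS for inj in injected]
    )
    prec_area = np.array([inj.area for inj in injected] * 2)
    prec_apex = np.array(
        [inj.apex_rt for inj in injected]
        + [inj.apex_rt + spec.underivatized_offset_min for inj in injected]
    )
    for t in ms1_times:
        inten = prec_area * norm * np.exp(-0.5 * ((t - prec_apex) / sig) ** 2)
        if spec.baseline > 0:
            inten = inten + rng.poisson(spec.baseline, size=inten.shape)
        run.ms1_scans.append(Scan(float(t), _jitter_mz(prec_mz.copy()), inten))

    # MS2: per channel, both members of every resident pair
    for ci, ch in enumerate(run.ms2_channels):
        residents = [inj for inj in injected if inj.channel_center == ch.center]
        phase = (ci + 1) * spec.ms2_interval_s / (len(run.ms2_channels) + 2) / 60.0
        times = np.arange(spec.rt_start + phase, spec.rt_end, spec.ms2_interval_s / 60.0)
        frag_mz = np.array(
            [m for inj in residents for m in (inj.pair.aldehyde_mz, inj.pair.alkene_mz)]
        )
        splits = np.array([s for _ in residents for s in spec.pair_split])
        areas = np.array([inj.area for inj in residents for _ in (0, 1)])
        apexes = np.array([inj.apex_rt for inj in residents for _ in (0, 1)])
        for t in times:
            inten = areas * splits * norm * np.exp(-0.5 * ((t - apexes) / sig) ** 2)
            if spec.baseline > 0:
                inten = inten + rng.poisson(spec.baseline, size=inten.shape)
            ch.scans.append(Scan(float(t), _jitter_mz(frag_mz.copy()), inten))

    truth = pd.DataFrame(
        {
            "species": [i.species_name for i in injected],
            "isomer": [i.full_name for i in injected],
            "position": [i.position for i in injected],
            "geometry": [i.geometry for i in injected],
            "label": [i.label or "" for i in injected],
            "apex_rt": [i.apex_rt for i in injected],
            "area": [i.area for i in injected],
            "area_nominal": [i.area_nominal for i in injected],
            "fraction": [i.fraction for i in injected],
            "channel_center": [i.channel_center for i in injected],
            "precursor_mz": [i.pair.precursor_mz for i in injected],
            "aldehyde_mz": [i.pair.aldehyde_mz for i in injected],
            "alkene_mz": [i.pair.alkene_mz for i in injected],
        }
    )
    return run, truth


#: the 14-isomer monounsaturated FA standard mixture used for validation
DEFAULT_STANDARD_PANEL: dict[str, list[SimIsomer]] = {
    "FA 16:1": [
        SimIsomer(7, "Z", 0.30),
        SimIsomer(9, "Z", 0.25),
        SimIsomer(9, "E", 0.15),
        SimIsomer(11, "Z", 0.20),
        SimIsomer(11, "E", 0.10),
    ],
    "FA 18:1": [
        SimIsomer(6, "Z", 0.20),
        SimIsomer(8, "Z", 0.15),
        SimIsomer(9, "Z", 0.25),
        SimIsomer(9, "E", 0.10),
        SimIsomer(10, "E", 0.05),
        SimIsomer(11, "Z", 0.15),
        SimIsomer(11, "E", 0.10),
    ],
    "FA 20:1": [
        SimIsomer(11, "Z", 0.60),
        SimIsomer(11, "E", 0.40),
    ],
}


def simulate_calibration_series(
    ratios: tuple[float, ...] = (99.0, 90.0, 50.0, 10.0, 1.0),
    noise_cv: float = 0.01,
    replicates: int = 3,
    seed: int = 0,
    response_e: float = 1.0,
    response_z: float = 1.0,
    total_area: float = 1.0e6,
) -> pd.DataFrame:
    """Simulate the cis/trans calibration mixtures (molar E fractions in %).

    Per replicate, the E and Z diagnostic-pair areas are proportional to
    molar fraction × response factor, each perturbed by multiplicative
    log-normal noise of sd ``noise_cv``.  The returned table feeds
    :func:`ccmeldi.quantify.fit_calibration` directly.
    """
    if not ratios:
        raise ValueError("ratio list must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    for molar_e in ratios:
        fe = molar_e / 100.0
        for rep in range(replicates):
            ne = math.exp(rng.normal(0.0, noise_cv)) if noise_cv > 0 else 1.0
            nz = math.exp(rng.normal(0.0, noise_cv)) if noise_cv > 0 else 1.0
            area_e = total_area * fe * response_e * ne
            area_z = total_area * (1.0 - fe) * response_z * nz
            rows.append(
                {
                    "molar_e_pct": molar_e,
                    "replicate": rep,
                    "area_e": area_e,
                    "area_z": area_z,
                    "area_fraction_pct": 100.0 * area_e / (area_e + area_z),
                }
            )
    return pd.DataFrame(rows)


def calibration_mixtures(table: pd.DataFrame) -> list[tuple[float, list[float]]]:
    """Group a calibration table into fit_calibration's mixture format."""
    out = []
    for molar, grp in table.groupby("molar_e_pct", sort=False):
        out.append((float(molar), grp["area_fraction_pct"].tolist()))
    return out


def simulate_tracer_timecourse(
    timepoints: tuple[float, ...] = (0.0, 5.0, 10.0, 24.0),
    conversion_per_interval: float = 0.3,
    labeled_amount: float = 2.0e5,
    background_9z: float = 8.0e5,
    background_10e: float = 1.0e5,
    istd_amount: float = 3.0e5,
    base_spec: SimSpec | None = None,
    seed: int = 0,
) -> tuple[list[tuple[float, TargetedRun]], pd.DataFrame]:
    """Simulate an isotope-tracking time course of 9Z→10E isomerization.

    A ¹³C₁-labeled 9Z pool (labels on the carboxyl-side C1–C9 segment, so
    the diagnostic fragments shift by +1) converts to labeled 10E at a
    fixed fraction of the remaining pool per sampling interval; unlabeled
    background isomers and a d17 internal standard (deuteriums on the
    methyl-side segment) stay constant.  Returns per-timepoint runs and a
    ground-truth table of amounts.
    """
    if not 0.0 <= conversion_per_interval <= 1.0:
        raise ValueError("conversion rate per interval must be in [0, 1]")
    runs: list[tuple[float, TargetedRun]] = []
    rows = []
    lab_9z = labeled_amount
    lab_10e = 0.0
    for k, t in enumerate(timepoints):
        if k > 0:
            moved = conversion_per_interval * lab_9z
            lab_9z -= moved
            lab_10e += moved
        total = background_9z + background_10e + lab_9z + lab_10e
        # drop zero-amount pools (e.g. labeled 10E at t0) and renormalize
        pools = [
            SimIsomer(9, "Z", background_9z / total),
            SimIsomer(10, "E", background_10e / total),
            SimIsomer(9, "Z", lab_9z / total, label="13C1@1-9"),
            SimIsomer(10, "E", lab_10e / total, label="13C1@1-10"),
        ]
        pools = [i for i in pools if i.molar_fraction > 0]
        rescale = sum(i.molar_fraction for i in pools)
        pools = [replace(i, molar_fraction=i.molar_fraction / rescale) for i in pools]
        spec = base_spec or SimSpec(panel={})
        spec = replace(
            spec,
            panel={"FA 18:1": pools, "FA 18:1[2H17@10-18]": [SimIsomer(9, "Z", 1.0)]},
            species_amount={"FA 18:1": total, "FA 18:1[2H17@10-18]": istd_amount},
            seed=seed + k,
        )
        run, _ = simulate_run(spec)
        runs.append((t, run))
        rows.append(
            {
                "time_h": t,
                "labeled_9z": lab_9z,
                "labeled_10e": lab_10e,
                "unlabeled_9z": background_9z,
                "unlabeled_10e": background_10e,
                "istd": istd_amount,
            }
        )
    return runs, pd.DataFrame(rows)
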