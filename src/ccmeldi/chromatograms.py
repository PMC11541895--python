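"""Targeted LC-MS/MS run handling: mzML I/O, EIC extraction, peak detection.

The acquisition emulated here interleaves full-scan MS1 (Orbitrap-class,
~10 ppm) with a short list of targeted ion-trap MS2 events (CID on the
epoxide precursors, ~0.3 Th fragment tolerance).  Retention times are
minutes throughout; seconds in files are converted on read.

Reading goes through :mod:`pyteomics.mzml`.  Writing (used by the run
simulator) is a minimal mzML 1.1 serializer — uncompressed 64-bit arrays,
enough controlled vocabulary for any mzML reader to route scans.
"""

from __future__ import annotations

import base64
import logging
import zlib
from dataclasses import dataclass, field
from typing import Sequence
from xml.sax.saxutils import escape

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Scan",
    "Ms2Channel",
    "TargetedRun",
    "Chromatogram",
    "Peak",
    "PairEvent",
    "PairMatching",
    "ChannelNotFoundError",
    "read_mzml",
    "write_mzml",
    "extract_eic",
    "detect_peaks",
    "match_pair_coelution",
]

DEFAULT_MS1_TOL_PPM = 10.0
DEFAULT_MS2_TOL_TH = 0.3


class ChannelNotFoundError(KeyError):
    """No targeted MS2 channel matches the requested precursor m/z."""


@dataclass
class Scan:
    rt: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays must have equal length")


@dataclass
class Ms2Channel:
    """All MS2 scans acquired for one isolation window."""

    center: float  # isolation center, Th
    width: float  # full isolation width, Th
    scans: list[Scan] = field(default_factory=list)

    def contains(self, mz: float) -> bool:
        return abs(mz - self.center) <= self.width / 2.0


@dataclass
class TargetedRun:
    """One targeted run: MS1 scans plus per-precursor MS2 channels."""

    ms1_scans: list[Scan] = field(default_factory=list)
    ms2_channels: list[Ms2Channel] = field(default_factory=list)
    orphan_ms2: list[Scan] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def channel_for(self, precursor_mz: float) -> Ms2Channel:
        hits = [c for c in self.ms2_channels if c.contains(precursor_mz)]
        if not hits:
            available = ", ".join(f"{c.center:.2f}±{c.width / 2:.2f}" for c in self.ms2_channels)
            raise ChannelNotFoundError(
                f"no MS2 channel covers m/z {precursor_mz:.4f}; available: [{available}]"
            )
        return min(hits, key=lambda c: abs(c.center - precursor_mz))

    def get_or_create_channel(self, center: float, width: float) -> Ms2Channel:
        for c in self.ms2_channels:
            if abs(c.center - center) <= c.width / 2.0:
                return c
        ch = Ms2Channel(center, width)
        self.ms2_channels.append(ch)
        return ch


@dataclass
class Chromatogram:
    """Extracted ion chromatogram: equal-length rt (min) / intensity arrays."""

    rt: np.ndarray
    intensity: np.ndarray
    query: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.shape != self.intensity.shape:
            raise ValueError("rt and intensity must have equal length")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class Peak:
    apex_rt: float
    area: float  # trapezoidal, counts·min
    height: float
    left_rt: float
    right_rt: float
    snr: float

    def __post_init__(self) -> None:
        if not self.left_rt <= self.apex_rt <= self.right_rt:
            raise ValueError("peak bounds must bracket the apex")


@dataclass
class PairEvent:
    """A co-eluting aldehyde/alkene diagnostic pair."""

    aldehyde: Peak
    alkene: Peak

    @property
    def apex_rt(self) -> float:
        return (self.aldehyde.apex_rt + self.alkene.apex_rt) / 2.0

    @property
    def pair_area(self) -> float:
        return self.aldehyde.area + self.alkene.area


@dataclass
class PairMatching:
    events: list[PairEvent]
    singleton_aldehydes: list[Peak]
    singleton_alkenes: list[Peak]


# ---------------------------------------------------------------------------
# mzML I/O

def _encode(arr: np.ndarray) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode("ascii")


_SPECTRUM_TMPL = """\
      <spectrum index="{index}" id="scan={scan}" defaultArrayLength="{n}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{level}"/>
        <cvParam cvRef="MS" accession="{kind_acc}" name="{kind_name}" value=""/>
        <cvParam cvRef="MS" accession="MS:1000129" name="negative scan" value=""/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <scanList count="1">
          <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt:.6f}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
          </scan>
        </scanList>
{precursor}        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{lmz}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{bmz}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{lint}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{bint}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""

_PRECURSOR_TMPL = """\
        <precursorList count="1">
          <precursor>
            <isolationWindow>
              <cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="{center:.6f}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
              <cvParam cvRef="MS" accession="MS:1000828" name="isolation window lower offset" value="{half:.6f}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
              <cvParam cvRef="MS" accession="MS:1000829" name="isolation window upper offset" value="{half:.6f}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            </isolationWindow>
            <selectedIonList count="1">
              <selectedIon>
                <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{center:.6f}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
              </selectedIon>
            </selectedIonList>
            <activation>
              <cvParam cvRef="MS" accession="MS:1000133" name="collision-induced dissociation" value=""/>
            </activation>
          </precursor>
        </precursorList>
"""


def write_mzml(run: TargetedRun, path: str) -> None:
    """Serialize a run to mzML 1.1 (uncompressed 64-bit float arrays).

    Deterministic: identical runs produce byte-identical files.
    """
    entries: list[tuple[float, int, int, float, float]] = []
    # (rt, level, ordering hint, center, width); MS1 before MS2 at equal rt
    scans: list[tuple[Scan, int, float, float]] = []
    for s in run.ms1_scans:
        scans.append((s, 1, 0.0, 0.0))
    for ch in run.ms2_channels:
        for s in ch.scans:
            scans.append((s, 2, ch.center, ch.width))
    scans.sort(key=lambda t: (t[0].rt, t[1], t[2]))

    parts = []
    for i, (s, level, center, width) in enumerate(scans):
        precursor = "" if level == 1 else _PRECURSOR_TMPL.format(center=center, half=width / 2.0)
        bmz, bint = _encode(s.mz), _encode(s.intensity)
        kind_acc, kind_name = ("MS:1000579", "MS1 spectrum") if level == 1 else ("MS:1000580", "MSn spectrum")
        parts.append(
            _SPECTRUM_TMPL.format(
                index=i, scan=i + 1, n=len(s.mz), level=level, rt=s.rt,
                precursor=precursor, bmz=bmz, bint=bint, lmz=len(bmz), lint=len(bint),
                kind_acc=kind_acc, kind_name=kind_name,
            )
        )
    meta_comment = ""
    if run.metadata:
        kv = " ".join(f"{k}={run.metadata[k]}" for k in sorted(run.metadata))
        meta_comment = f"  <!-- ccmeldi run metadata: {escape(kv)} -->\n"
    doc = (
        '<?xml version="1.0" encoding="utf-8"?>\n'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n'
        + meta_comment +
        '  <cvList count="2">\n'
        '    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>\n'
        '    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>\n'
        "  </cvList>\n"
        '  <fileDescription><fileContent>\n'
        '    <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>\n'
        "  </fileContent></fileDescription>\n"
        '  <softwareList count="1"><software id="ccmeldi" version="0.1.0"/></softwareList>\n'
        '  <instrumentConfigurationList count="1"><instrumentConfiguration id="IC1"/></instrumentConfigurationList>\n'
        '  <dataProcessingList count="1"><dataProcessing id="dp1"><processingMethod order="1" softwareRef="ccmeldi">\n'
        '    <cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>\n'
        "  </processingMethod></dataProcessing></dataProcessingList>\n"
        f'  <run id="run1" defaultInstrumentConfigurationRef="IC1">\n'
        f'    <spectrumList count="{len(scans)}" defaultDataProcessingRef="dp1">\n'
        + "".join(parts)
        + "    </spectrumList>\n  </run>\n</mzML>\n"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(doc)


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(elem) -> dict[str, tuple[str, str]]:
    """name → (value, unitName) for direct cvParam children."""
    out = {}
    for child in elem:
        if _local(child.tag) == "cvParam":
            out[child.get("name", "")] = (child.get("value", ""), child.get("unitName", ""))
    return out


def _find(elem, *path: str):
    """Namespace-agnostic nested find of the first matching child chain."""
    cur = elem
    for name in path:
        nxt = None
        for child in cur:
            if _local(child.tag) == name:
                nxt = child
                break
        if nxt is None:
            return None
        cur = nxt
    return cur


def _decode_binary_array(bda) -> np.ndarray | None:
    params = _cv_params(bda)
    binary = _find(bda, "binary")
    raw = base64.b64decode((binary.text or "").strip()) if binary is not None else b""
    if "zlib compression" in params:
        raw = zlib.decompress(raw)
    dtype = "<f4" if "32-bit float" in params else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_spectrum(elem) -> tuple[Scan, int, float | None, float]:
    params = _cv_params(elem)
    level = int(params.get("ms level", ("1", ""))[0] or 1)

    rt = 0.0
    scan_el = _find(elem, "scanList", "scan")
    if scan_el is not None:
        sp = _cv_params(scan_el)
        if "scan start time" in sp:
            value, unit = sp["scan start time"]
            rt = float(value)
            if unit.lower().startswith("second"):
                rt /= 60.0

    center, width = None, 1.0
    iso = _find(elem, "precursorList", "precursor", "isolationWindow")
    if iso is not None:
        ip = _cv_params(iso)
        if "isolation window target m/z" in ip:
            center = float(ip["isolation window target m/z"][0])
            lo = float(ip.get("isolation window lower offset", ("0.5", ""))[0])
            hi = float(ip.get("isolation window upper offset", ("0.5", ""))[0])
            width = lo + hi

    mz = inten = None
    bdal = _find(elem, "binaryDataArrayList")
    if bdal is not None:
        for bda in bdal:
            if _local(bda.tag) != "binaryDataArray":
                continue
            p = _cv_params(bda)
            arr = _decode_binary_array(bda)
            if "m/z array" in p:
                mz = arr
            elif "intensity array" in p:
                inten = arr
    if mz is None or inten is None:
        mz = np.empty(0)
        inten = np.empty(0)
    return Scan(rt, mz, inten), level, center, width


def read_mzml(path: str) -> TargetedRun:
    """Load an mzML file, routing MS2 scans to targeted channels.

    A scan joins the channel whose isolation center it falls within (half
    the isolation width); MS2 scans without usable precursor metadata are
    kept in ``orphan_ms2`` and logged.  Handles the mzML 1.1 subset this
    workflow consumes: centroided spectra, 32/64-bit float arrays, zlib
    or no compression, scan times in minutes or seconds.
    """
    import xml.etree.ElementTree as ET

    run = TargetedRun(metadata={"source": str(path)})
    for _, elem in ET.iterparse(path, events=("end",)):
        if _local(elem.tag) != "spectrum":
            continue
        s, level, center, width = _parse_spectrum(elem)
        if level == 1:
            run.ms1_scans.append(s)
        elif center is None:
            logger.warning(
                "MS2 scan at %.3f min lacks precursor metadata; kept as orphan", s.rt
            )
            run.orphan_ms2.append(s)
        else:
            run.get_or_create_channel(center, width).scans.append(s)
        elem.clear()
    for ch in run.ms2_channels:
        ch.scans.sort(key=lambda s: s.rt)
    run.ms1_scans.sort(key=lambda s: s.rt)
    run.metadata["polarity"] = "negative"
    return run


# ---------------------------------------------------------------------------
# EIC extraction

def extract_eic(
    run: TargetedRun,
    level: int,
    precursor_mz: float | None,
    target_mz: float,
    tol: float | None = None,
) -> Chromatogram:
    """Extract an ion chromatogram at MS1 or MS2 level.

    ``tol`` is ppm at MS1 (default 10) and Th at MS2 (default 0.3).  Per
    scan, intensity is the sum over points with \\|m/z − target\\| ≤ tol.
    """
    if level == 1:
        tol_ppm = DEFAULT_MS1_TOL_PPM if tol is None else tol
        half = target_mz * tol_ppm * 1e-6
        scans = run.ms1_scans
    elif level == 2:
        half = DEFAULT_MS2_TOL_TH if tol is None else tol
        if precursor_mz is None:
            raise ValueError("MS2 extraction requires a precursor m/z")
        scans = run.channel_for(precursor_mz).scans
    else:
        raise ValueError(f"unsupported MS level {level}")

    rt = np.array([s.rt for s in scans])
    inten = np.array(
        [s.intensity[np.abs(s.mz - target_mz) <= half].sum() for s in scans]
    )
    return Chromatogram(
        rt, inten,
        query={"level": level, "precursor_mz": precursor_mz, "target_mz": target_mz, "tol": half},
    )


# ---------------------------------------------------------------------------
# peak detection

def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.copy()
    kernel = np.ones(window) / window
    return np.convolve(np.pad(x, window // 2, mode="edge"), kernel, mode="same")[
        window // 2 : window // 2 + len(x)
    ]


def detect_peaks(
    chrom: Chromatogram,
    smooth_window: int = 5,
    noise_k: float = 3.0,
    min_snr: float = 3.0,
    min_points: int = 4,
) -> list[Peak]:
    """Detect and integrate chromatographic peaks.

    Moving-average smoothing; local maxima above a robust noise floor
    (median + ``noise_k``·MAD of the trace); boundaries at flanking minima
    or baseline crossings; trapezoidal area on the *raw* trace.  Returns
    peaks sorted by apex RT.
    """
    y = chrom.intensity
    if len(y) < max(smooth_window, min_points):
        logger.warning("trace of %d points shorter than window; no peaks", len(y))
        return []
    sm = _moving_average(y, smooth_window)
    med = float(np.median(sm))
    mad = float(np.median(np.abs(sm - med)))
    sigma = 1.4826 * mad
    floor = med + noise_k * mad
    if floor <= 0:
        floor = 1e-12  # noiseless traces: anything above zero is signal

    from scipy.signal import find_peaks as _find_peaks

    idx, _ = _find_peaks(sm, height=floor)
    peaks: list[Peak] = []
    for i in idx:
        left = i
        while left > 0 and sm[left - 1] < sm[left] and sm[left - 1] > floor * 0.05:
            left -= 1
        while left > 0 and sm[left - 1] <= sm[left] and sm[left] > floor * 0.05:
            left -= 1
        right = i
        n = len(sm)
        while right < n - 1 and sm[right + 1] < sm[right] and sm[right + 1] > floor * 0.05:
            right += 1
        while right < n - 1 and sm[right + 1] <= sm[right] and sm[right] > floor * 0.05:
            right += 1
        if right - left + 1 < min_points:
            continue
        height = float(y[left : right + 1].max())
        snr = height / sigma if sigma > 0 else float("inf")
        if snr < min_snr:
            continue
        apex = left + int(np.argmax(y[left : right + 1]))
        area = float(np.trapezoid(y[left : right + 1], chrom.rt[left : right + 1]))
        peaks.append(
            Peak(
                apex_rt=float(chrom.rt[apex]),
                area=area,
                height=height,
                left_rt=float(chrom.rt[left]),
                right_rt=float(chrom.rt[right]),
                snr=snr,
            )
        )
    # merge duplicates sharing an apex (plateaus)
    uniq: dict[float, Peak] = {}
    for p in peaks:
        uniq.setdefault(p.apex_rt, p)
    return sorted(uniq.values(), key=lambda p: p.apex_rt)


def match_pair_coelution(
    aldehyde_peaks: Sequence[Peak],
    alkene_peaks: Sequence[Peak],
    rt_tol: float = 0.1,
) -> PairMatching:
    """Greedily pair aldehyde and alkene peaks by nearest apex within ``rt_tol``.

    Candidate pairs are taken in order of apex distance, so the pairing is
    symmetric in its two arguments.  Unmatched peaks on either side are
    reported as singletons and should not feed confident assignments.
    """
    cands = [
        (abs(a.apex_rt - b.apex_rt), i, j)
        for i, a in enumerate(aldehyde_peaks)
        for j, b in enumerate(alkene_peaks)
        if abs(a.apex_rt - b.apex_rt) <= rt_tol
    ]
    cands.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    events = []
    for _, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        events.append(PairEvent(aldehyde_peaks[i], alkene_peaks[j]))
    events.sort(key=lambda e: e.apex_rt)
    return PairMatching(
        events=events,
        singleton_aldehydes=[p for i, p in enumerate(aldehyde_peaks) if i not in used_a],
        singleton_alkenes=[p for j, p in enumerate(alkene_peaks) if j not in used_b],
    )
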