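"""Pseudo-MS/MS reconstruction and carbon-isotopologue assignment.

In an AIF run every high-energy scan contains fragments of everything
eluting at that moment. Fragments belonging to one parent share its elution
profile, so the extracted ion chromatogram (EIC) of a true fragment channel
correlates strongly with the parent's MS1 EIC. A pseudo-MS/MS spectrum for
a target feature is therefore built by correlating every AIF m/z channel
in the feature's RT window against the feature's MS1 EIC and keeping
channels with Pearson r above a user threshold theta (default 0.8). When no
channel passes, the raw AIF spectrum at the feature RT is substituted
(flagged as a fallback).

Fragment libraries hold monoisotopic masses only, so a feature sitting on
an M+1..M+k carbon isotopologue peak must first be walked down to its
monoisotopic (M+0) m/z: among correlated MS1 peaks, step down in units of
the 13C-12C mass difference (1.00336 Th) while a more intense peak exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .mzml import AIF, MS1, EIC, RawRun, Spectrum, extract_eic, list_peaks, spectrum_near

__all__ = [
    "Feature",
    "PseudoPeak",
    "PseudoSpectrum",
    "IsotopologueAssignment",
    "pearson_r",
    "build_pseudo_msms",
    "assign_isotopologue",
    "CARBON_ISOTOPE_SPACING",
]

logger = logging.getLogger(__name__)

#: 13C - 12C mass difference (Th, singly charged).
CARBON_ISOTOPE_SPACING = 1.00336

DEFAULT_THETA = 0.8
DEFAULT_RT_HALF_WIDTH = 10.0  # seconds
DEFAULT_EIC_TOL = 0.01  # Th
DEFAULT_MIN_POINTS = 5
DEFAULT_R_ISO = 0.8
DEFAULT_MAX_K = 5


@dataclass(frozen=True)
class Feature:
    """A target m/z-RT pair to annotate."""

    mz: float
    rt: float
    id: str = ""
    intensity: float | None = None

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"feature m/z must be positive, got {self.mz}")


@dataclass(frozen=True)
class PseudoPeak:
    """One AIF channel admitted to a pseudo-MS/MS spectrum."""

    mz: float
    intensity: float  # apex intensity of the channel EIC in the RT window
    r: float | None  # Pearson correlation to the feature EIC; None for fallback peaks


@dataclass
class PseudoSpectrum:
    """Correlation-linked fragment peaks for one feature.

    ``is_fallback`` is True when no channel passed the correlation threshold
    and the raw AIF spectrum at the feature RT was substituted; fallback
    peaks carry ``r = None``.
    """

    feature: Feature
    peaks: list[PseudoPeak]
    is_fallback: bool
    theta: float

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)
        # imported (precomputed) spectra carry theta = NaN and unknown r
        if not self.is_fallback and not np.isnan(self.theta):
            bad = [p for p in self.peaks if p.r is None or not p.r > self.theta]
            if bad:
                raise ValueError("non-fallback pseudo-MS/MS peak below threshold")

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class IsotopologueAssignment:
    """Which isotope peak (M+k) a feature sits on, and the corrected M+0 m/z."""

    offset: int
    monoisotopic_mz: float
    evidence: list[tuple[float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError("isotopologue offset must be >= 0")


def pearson_r(x: EIC | np.ndarray, y: EIC | np.ndarray, min_points: int = 2) -> float | None:
    """Pearson correlation of two intensity vectors on a shared RT grid.

    Returns None (undefined) when either vector is constant or fewer than
    ``min_points`` points overlap; callers treat None as below any
    threshold.
    """
    xv = np.asarray(x.intensities if isinstance(x, EIC) else x, dtype=float)
    yv = np.asarray(y.intensities if isinstance(y, EIC) else y, dtype=float)
    if xv.shape != yv.shape:
        raise ValueError("EICs must be resampled to the same RT grid")
    if xv.size < max(2, min_points):
        return None
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    sx = float(np.sqrt(np.dot(xc, xc)))
    sy = float(np.sqrt(np.dot(yc, yc)))
    if sx == 0.0 or sy == 0.0:
        return None
    r = float(np.dot(xc, yc) / (sx * sy))
    return max(-1.0, min(1.0, r))


def _bin_aif_channels(scans: list[Spectrum], tol: float) -> np.ndarray:
    """Group peak m/z values across scans into channels by greedy clustering.

    Channels are seeded by the most intense peaks (m/z ascending on ties)
    and a peak joins the nearest existing channel within ``tol``; the
    channel m/z stays at its seed. Deterministic and independent of scan
    order.
    """
    if not scans:
        return np.empty(0)
    all_mz = np.concatenate([s.mz for s in scans])
    all_int = np.concatenate([s.intensity for s in scans])
    if all_mz.size == 0:
        return np.empty(0)
    order = np.lexsort((all_mz, -all_int))
    channels: list[float] = []  # kept sorted
    import bisect

    for idx in order:
        m = float(all_mz[idx])
        pos = bisect.bisect_left(channels, m)
        nearest = None
        if pos < len(channels):
            nearest = channels[pos]
        if pos > 0 and (nearest is None or m - channels[pos - 1] < nearest - m):
            nearest = channels[pos - 1]
        if nearest is None or abs(m - nearest) > tol:
            bisect.insort(channels, m)
    return np.asarray(channels)


def _feature_ms1_eic(
    run: RawRun, feature: Feature, rt_window: tuple[float, float], eic_tol: float
) -> EIC:
    return extract_eic(run, MS1, feature.mz, tol=eic_tol, rt_window=rt_window)


def build_pseudo_msms(
    run: RawRun,
    feature: Feature,
    theta: float = DEFAULT_THETA,
    rt_half_width: float = DEFAULT_RT_HALF_WIDTH,
    eic_tol: float = DEFAULT_EIC_TOL,
    min_points: int = DEFAULT_MIN_POINTS,
    fallback_min_intensity: float = 0.0,
) -> PseudoSpectrum:
    """Build the pseudo-MS/MS spectrum of ``feature`` by EIC correlation.

    Every distinct AIF peak m/z (binned to ``eic_tol``) within the feature's
    RT window defines a candidate channel; channels whose AIF EIC,
    interpolated onto the MS1 scan grid, correlates with the feature's MS1
    EIC at r > theta become pseudo-MS/MS peaks (intensity = channel apex in
    the window). When no channel passes — or the feature's own EIC is flat —
    the raw AIF spectrum near the feature RT is returned with
    ``is_fallback = True``.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must be in [0, 1]")
    window = (feature.rt - rt_half_width, feature.rt + rt_half_width)
    lo, hi = run.rt_range
    if not (lo <= feature.rt <= hi):
        raise ValueError(f"feature RT {feature.rt} outside run range ({lo}, {hi})")

    def _fallback(reason: str) -> PseudoSpectrum:
        logger.warning("feature %s m/z %.4f: %s; using raw AIF spectrum",
                       feature.id or "?", feature.mz, reason)
        spec = spectrum_near(run, AIF, feature.rt, n_scans=3, merge_tol=eic_tol)
        peaks = [PseudoPeak(mz, inten, None)
                 for mz, inten in list_peaks(spec, fallback_min_intensity)]
        return PseudoSpectrum(feature=feature, peaks=peaks, is_fallback=True, theta=theta)

    feat_eic = _feature_ms1_eic(run, feature, window, eic_tol)
    if feat_eic.apex_intensity <= 0:
        return _fallback("feature MS1 EIC is all zero")

    aif_scans = run.scans_in_window(AIF, window)
    channels = _bin_aif_channels(aif_scans, eic_tol)
    peaks: list[PseudoPeak] = []
    for ch_mz in channels:
        ch_eic = extract_eic(run, AIF, float(ch_mz), tol=eic_tol, rt_window=window)
        # AIF scans interleave with MS1 scans; resample onto the MS1 grid
        resampled = np.interp(feat_eic.rts, ch_eic.rts, ch_eic.intensities)
        r = pearson_r(feat_eic.intensities, resampled, min_points=min_points)
        if r is not None and r > theta:
            peaks.append(PseudoPeak(float(ch_mz), ch_eic.apex_intensity, r))
    if not peaks:
        return _fallback(f"no AIF channel correlated above theta={theta}")
    return PseudoSpectrum(feature=feature, peaks=peaks, is_fallback=False, theta=theta)


def assign_isotopologue(
    run: RawRun,
    feature: Feature,
    r_iso: float = DEFAULT_R_ISO,
    delta_c: float = CARBON_ISOTOPE_SPACING,
    max_k: int = DEFAULT_MAX_K,
    rt_half_width: float = DEFAULT_RT_HALF_WIDTH,
    eic_tol: float = DEFAULT_EIC_TOL,
    min_points: int = DEFAULT_MIN_POINTS,
) -> IsotopologueAssignment:
    """Determine which carbon isotopologue (M+k) the feature m/z sits on.

    Starting from the feature m/z, repeatedly look for an MS1 peak one
    carbon-isotope spacing below the current one whose EIC correlates with
    the feature EIC at r > r_iso and whose apex intensity exceeds the
    current peak's; each successful step increments the offset k (capped at
    ``max_k``). The corrected monoisotopic m/z is snapped to the observed
    peak m/z. Features with no such lower-mass peak are monoisotopic
    (offset 0).
    """
    window = (feature.rt - rt_half_width, feature.rt + rt_half_width)
    feat_eic = _feature_ms1_eic(run, feature, window, eic_tol)
    ms1_spec = spectrum_near(run, MS1, feature.rt, n_scans=3, merge_tol=eic_tol)

    def _nearest_peak(target: float) -> float | None:
        if not len(ms1_spec):
            return None
        idx = int(np.argmin(np.abs(ms1_spec.mz - target)))
        mz = float(ms1_spec.mz[idx])
        return mz if abs(mz - target) <= eic_tol else None

    current_mz = feature.mz
    snapped = _nearest_peak(feature.mz)
    if snapped is not None:
        current_mz = snapped
    current_apex = extract_eic(run, MS1, current_mz, tol=eic_tol,
                               rt_window=window).apex_intensity
    offset = 0
    evidence: list[tuple[float, float, float]] = []
    while offset < max_k:
        target = feature.mz - (offset + 1) * delta_c
        lower_mz = _nearest_peak(target)
        if lower_mz is None:
            break
        lower_eic = extract_eic(run, MS1, lower_mz, tol=eic_tol, rt_window=window)
        r = pearson_r(feat_eic.intensities, lower_eic.intensities, min_points=min_points)
        if r is None or not r > r_iso:
            break
        if not lower_eic.apex_intensity > current_apex:
            break
        offset += 1
        current_mz = lower_mz
        current_apex = lower_eic.apex_intensity
        evidence.append((lower_mz, lower_eic.apex_intensity, r))
    return IsotopologueAssignment(offset=offset, monoisotopic_mz=current_mz,
                                  evidence=evidence)


def load_pseudo_msp(path) -> list[PseudoSpectrum]:
    """Load precomputed pseudo-MS/MS spectra from an MSP file.

    One entry per feature: the precursor m/z is the feature m/z, the
    retention time (seconds) is taken from a ``RETENTIONTIME``/``RT`` field
    or a ``COMMENT: RT=<seconds>`` annotation, and the peak list supplies
    the pseudo-MS/MS peaks (r is unknown for imported spectra). This input
    replaces EIC-based reconstruction; no chromatograms exist downstream.
    """
    import re as _re
    from pathlib import Path as _Path

    path = _Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"MSP file not found: {path}")
    spectra: list[PseudoSpectrum] = []
    current: dict | None = None
    peak_re = _re.compile(r"^\s*(\d+\.?\d*(?:[eE][+-]?\d+)?)[\s,;]+(\d+\.?\d*(?:[eE][+-]?\d+)?)")

    def _flush(entry: dict | None) -> None:
        if entry is None:
            return
        if entry.get("precursor") is None:
            logger.warning("pseudo-MS/MS MSP entry %r lacks a precursor; skipped",
                           entry.get("name"))
            return
        feature = Feature(mz=entry["precursor"], rt=entry.get("rt") or 0.0,
                          id=entry.get("name", ""))
        peaks = [PseudoPeak(mz, inten, None) for mz, inten in entry["peaks"]]
        spectra.append(PseudoSpectrum(feature=feature, peaks=peaks,
                                      is_fallback=False, theta=float("nan")))

    with open(path, encoding="utf-8", errors="replace") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if ":" in line and not peak_re.match(line):
                key, _, value = line.partition(":")
                key = key.strip().lower()
                value = value.strip()
                if key == "name":
                    _flush(current)
                    current = {"name": value, "precursor": None, "rt": None, "peaks": []}
                elif current is None:
                    continue
                elif key in ("precursormz", "precursor_mz", "precursor"):
                    try:
                        current["precursor"] = float(value)
                    except ValueError:
                        pass
                elif key in ("retentiontime", "rt", "rtinseconds"):
                    try:
                        current["rt"] = float(value)
                    except ValueError:
                        pass
                elif key in ("comment", "comments"):
                    m = _re.search(r"RT=([0-9.eE+-]+)", value)
                    if m:
                        current["rt"] = float(m.group(1))
                continue
            m = peak_re.match(line)
            if m and current is not None:
                current["peaks"].append((float(m.group(1)), float(m.group(2))))
    _flush(current)
    return spectra
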