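"""Raw AIF LC-MS run I/O: mzML read/write, channel splitting, EICs.

All-ion-fragmentation (MSE / bbCID / MS/MSALL) runs alternate low-collision-
energy scans (here the "MS1" channel) with high-energy fragmenting scans
(the "AIF" channel) with no precursor isolation. Converters encode the
high-energy function inconsistently — as msLevel 2, as a nonzero collision
energy, or not at all — so the channel split rule is configurable.

The mzML 1.1 codec here is deliberately minimal (centroided spectra,
32/64-bit float arrays, zlib or no compression, scan times in seconds or
minutes) and built on the standard library so the package has no
mass-spectrometry I/O dependency.
"""

from __future__ import annotations

import base64
import struct
import xml.etree.ElementTree as ET
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "Spectrum",
    "RawRun",
    "EIC",
    "MzmlError",
    "centroid_profile",
    "read_aif_run",
    "write_mzml",
    "extract_eic",
    "spectrum_near",
    "list_peaks",
]

MS1 = "MS1"
AIF = "AIF"

Channel = Literal["MS1", "AIF"]


class MzmlError(RuntimeError):
    """Unreadable file or a run that cannot be processed as AIF."""


@dataclass
class Spectrum:
    """One centroided scan: retention time, channel, and (mz, intensity) peaks."""

    rt: float  # seconds
    channel: str
    mz: np.ndarray
    intensity: np.ndarray
    ms_level: int = 1
    collision_energy: float | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities")

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass
class RawRun:
    """An AIF run split into time-ordered MS1 and AIF scan lists."""

    ms1_scans: list[Spectrum]
    aif_scans: list[Spectrum]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for scans, name in ((self.ms1_scans, "MS1"), (self.aif_scans, "AIF")):
            rts = [s.rt for s in scans]
            if any(b <= a for a, b in zip(rts, rts[1:])):
                raise ValueError(f"{name} scan times must be strictly increasing")
        self._rt_cache: dict[str, list[float]] = {}

    def scans(self, channel: str) -> list[Spectrum]:
        if channel == MS1:
            return self.ms1_scans
        if channel == AIF:
            return self.aif_scans
        raise ValueError(f"unknown channel {channel!r}")

    def scans_in_window(self, channel: str, rt_window: tuple[float, float]) -> list[Spectrum]:
        """Scans with rt in [lo, hi]; binary search on the (sorted) scan times."""
        import bisect

        scans = self.scans(channel)
        rts = self._rt_cache.get(channel)
        if rts is None or len(rts) != len(scans):
            rts = [s.rt for s in scans]
            self._rt_cache[channel] = rts
        lo, hi = rt_window
        i = bisect.bisect_left(rts, lo)
        j = bisect.bisect_right(rts, hi)
        return scans[i:j]

    @property
    def rt_range(self) -> tuple[float, float]:
        rts = [s.rt for s in self.ms1_scans + self.aif_scans]
        return (min(rts), max(rts))


@dataclass
class EIC:
    """Extracted ion chromatogram of one narrow m/z channel."""

    mz_target: float
    tol: float
    rts: np.ndarray
    intensities: np.ndarray
    channel: str

    def __post_init__(self) -> None:
        self.rts = np.asarray(self.rts, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.rts.shape != self.intensities.shape:
            raise ValueError("rts and intensities must have equal length")
        if self.rts.size > 1 and np.any(np.diff(self.rts) <= 0):
            raise ValueError("EIC retention times must be strictly increasing")

    @property
    def apex_rt(self) -> float:
        return float(self.rts[int(np.argmax(self.intensities))])

    @property
    def apex_intensity(self) -> float:
        return float(self.intensities.max(initial=0.0))

    def __len__(self) -> int:
        return int(self.rts.size)


# ---------------------------------------------------------------------------
# mzML reading

_ACC_MS_LEVEL = "MS:1000511"
_ACC_PROFILE = "MS:1000128"
_ACC_SCAN_START = "MS:1000016"
_ACC_COLLISION_E = "MS:1000045"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NOCOMP = "MS:1000576"


def _strip_ns(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_array(bda: ET.Element) -> np.ndarray:
    dtype = np.float64
    compressed = False
    kind = None
    payload = b""
    for el in bda.iter():
        t = _strip_ns(el.tag)
        if t == "cvParam":
            acc = el.get("accession", "")
            if acc == _ACC_F32:
                dtype = np.float32
            elif acc == _ACC_F64:
                dtype = np.float64
            elif acc == _ACC_ZLIB:
                compressed = True
            elif acc == _ACC_MZ_ARRAY:
                kind = "mz"
            elif acc == _ACC_INT_ARRAY:
                kind = "intensity"
        elif t == "binary" and el.text:
            payload = base64.b64decode(el.text.strip())
    if compressed and payload:
        payload = zlib.decompress(payload)
    arr = np.frombuffer(payload, dtype=dtype).astype(float)
    bda.set("_kind", kind or "")
    return arr


def centroid_profile(mz: np.ndarray, intensity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid a profile trace by local-maximum picking.

    Each region between consecutive local minima (valleys, including
    zero-intensity gaps) that contains a local maximum becomes one centroid:
    m/z is the intensity-weighted mean of the region, intensity its sum.
    Deterministic; plateaus resolve to their leftmost point.
    """
    n = mz.size
    if n < 3:
        return mz.copy(), intensity.copy()
    valleys = [0]
    for i in range(1, n - 1):
        if intensity[i] <= intensity[i - 1] and intensity[i] < intensity[i + 1]:
            valleys.append(i)
    valleys.append(n - 1)
    out_mz: list[float] = []
    out_int: list[float] = []
    for lo, hi in zip(valleys, valleys[1:]):
        seg_i = intensity[lo:hi + 1]
        seg_m = mz[lo:hi + 1]
        total = float(seg_i.sum())
        if total <= 0 or seg_i.max() <= 0:
            continue
        out_mz.append(float(np.average(seg_m, weights=seg_i)))
        out_int.append(total)
    return np.asarray(out_mz), np.asarray(out_int)


def _parse_spectrum(elem: ET.Element) -> tuple[float, int, float | None, np.ndarray, np.ndarray]:
    ms_level = 1
    rt = None
    collision_energy = None
    is_profile = False
    mz = np.empty(0)
    inten = np.empty(0)
    for el in elem.iter():
        t = _strip_ns(el.tag)
        if t == "cvParam":
            acc = el.get("accession", "")
            if acc == _ACC_MS_LEVEL:
                ms_level = int(el.get("value", "1"))
            elif acc == _ACC_PROFILE:
                is_profile = True
            elif acc == _ACC_SCAN_START:
                value = float(el.get("value", "nan"))
                unit = (el.get("unitName") or "").lower()
                rt = value * 60.0 if unit.startswith("min") else value
            elif acc == _ACC_COLLISION_E:
                collision_energy = float(el.get("value", "0"))
        elif t == "binaryDataArray":
            arr = _decode_array(el)
            if el.get("_kind") == "mz":
                mz = arr
            elif el.get("_kind") == "intensity":
                inten = arr
    if rt is None:
        raise MzmlError("spectrum without a scan start time")
    if is_profile:
        mz, inten = centroid_profile(mz, inten)
    return rt, ms_level, collision_energy, mz, inten


def _iter_mzml_spectra(path: Path):
    try:
        context = ET.iterparse(str(path), events=("end",))
        for _, elem in context:
            if _strip_ns(elem.tag) == "spectrum":
                yield _parse_spectrum(elem)
                elem.clear()
    except (ET.ParseError, OSError) as exc:
        raise MzmlError(f"cannot read mzML file {path}: {exc}") from exc


def _make_split_rule(split_rule: str):
    """Build a scan -> channel classifier from a rule token.

    Recognized tokens: ``mslevel`` (msLevel 1 vs 2, the default),
    ``ce:<threshold>`` (collision energy above threshold -> AIF), and
    ``alternate`` (even/odd scan parity).
    """
    rule = (split_rule or "mslevel").strip().lower()
    if rule == "mslevel":
        return lambda i, ms_level, ce: AIF if ms_level >= 2 else MS1
    if rule.startswith("ce"):
        threshold = float(rule.split(":", 1)[1]) if ":" in rule else 0.0
        return lambda i, ms_level, ce: AIF if (ce or 0.0) > threshold else MS1
    if rule == "alternate":
        return lambda i, ms_level, ce: MS1 if i % 2 == 0 else AIF
    raise ValueError(f"unknown split rule {split_rule!r}")


def read_aif_run(path: str | Path, split_rule: str = "mslevel") -> RawRun:
    """Read an mzML AIF run and split scans into MS1 and AIF channels.

    Raises :class:`MzmlError` when the file is unreadable or when the split
    leaves one channel empty (the file is then not processable as AIF).
    """
    path = Path(path)
    if not path.is_file():
        raise MzmlError(f"mzML file not found: {path}")
    classify = _make_split_rule(split_rule)
    ms1: list[Spectrum] = []
    aif: list[Spectrum] = []
    for i, (rt, ms_level, ce, mz, inten) in enumerate(_iter_mzml_spectra(path)):
        channel = classify(i, ms_level, ce)
        spec = Spectrum(rt=rt, channel=channel, mz=mz, intensity=inten,
                        ms_level=ms_level, collision_energy=ce)
        (ms1 if channel == MS1 else aif).append(spec)
    if not ms1 or not aif:
        raise MzmlError(
            f"not an AIF run: split rule {split_rule!r} yielded "
            f"{len(ms1)} MS1 and {len(aif)} AIF scans in {path}"
        )
    return RawRun(ms1_scans=ms1, aif_scans=aif,
                  metadata={"path": str(path), "split_rule": split_rule,
                            "n_ms1": len(ms1), "n_aif": len(aif)})


# ---------------------------------------------------------------------------
# mzML writing

_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <run id="{run_id}">
    <spectrumList count="{count}">
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _encode_array(values: np.ndarray, compress: bool) -> str:
    raw = np.asarray(values, dtype=np.float64).tobytes()
    if compress:
        raw = zlib.compress(raw)
    return base64.b64encode(raw).decode("ascii")


def write_mzml(
    path: str | Path,
    scans: Sequence[Spectrum],
    run_id: str = "synthetic_aif_run",
    encode_channels: str = "mslevel",
    compress: bool = True,
) -> Path:
    """Write centroided scans as mzML 1.1.

    ``encode_channels`` controls how the AIF channel is marked in the file:
    ``mslevel`` writes AIF scans at msLevel 2 with a collision energy;
    ``ce_only`` leaves all scans at msLevel 1 and distinguishes channels by
    collision energy alone (0 vs 30 eV), matching converters that do not
    bump the msLevel of the high-energy function.
    """
    if encode_channels not in ("mslevel", "ce_only"):
        raise ValueError(f"unknown channel encoding {encode_channels!r}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_MZML_HEADER.format(run_id=run_id, count=len(scans)))
        for i, spec in enumerate(scans):
            is_aif = spec.channel == AIF
            ms_level = 2 if (is_aif and encode_channels == "mslevel") else 1
            ce = spec.collision_energy
            if ce is None:
                ce = 30.0 if is_aif else 0.0
            mz_b64 = _encode_array(spec.mz, compress)
            int_b64 = _encode_array(spec.intensity, compress)
            comp_param = (
                '<cvParam cvRef="MS" accession="MS:1000574" name="zlib compression"/>'
                if compress
                else '<cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>'
            )
            fh.write(
                f'      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(spec)}">\n'
                f'        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{ms_level}"/>\n'
                f'        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum"/>\n'
                f'        <scanList count="1">\n'
                f'          <scan>\n'
                f'            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
                f'value="{spec.rt!r}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>\n'
                f'            <cvParam cvRef="MS" accession="MS:1000045" name="collision energy" '
                f'value="{ce!r}" unitCvRef="UO" unitAccession="UO:0000266" unitName="electronvolt"/>\n'
                f'          </scan>\n'
                f'        </scanList>\n'
                f'        <binaryDataArrayList count="2">\n'
                f'          <binaryDataArray encodedLength="{len(mz_b64)}">\n'
                f'            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>\n'
                f'            {comp_param}\n'
                f'            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array"/>\n'
                f'            <binary>{mz_b64}</binary>\n'
                f'          </binaryDataArray>\n'
                f'          <binaryDataArray encodedLength="{len(int_b64)}">\n'
                f'            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>\n'
                f'            {comp_param}\n'
                f'            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array"/>\n'
                f'            <binary>{int_b64}</binary>\n'
                f'          </binaryDataArray>\n'
                f'        </binaryDataArrayList>\n'
                f'      </spectrum>\n'
            )
        fh.write(_MZML_FOOTER)
    return path


# ---------------------------------------------------------------------------
# Chromatogram / spectrum access

def extract_eic(
    run: RawRun,
    channel: str,
    mz_target: float,
    tol: float = 0.01,
    rt_window: tuple[float, float] | None = None,
) -> EIC:
    """Extract the ion chromatogram of ``mz_target`` +/- ``tol``.

    One point per scan inside ``rt_window`` (whole run when None); the point
    intensity is the sum of all peak intensities within the m/z tolerance,
    zero when nothing matches. Raises ``ValueError`` when the window
    contains no scans.
    """
    if rt_window is not None:
        scans = run.scans_in_window(channel, rt_window)
    else:
        scans = run.scans(channel)
    if not scans:
        raise ValueError(f"no {channel} scans in RT window {rt_window}")
    rts = np.array([s.rt for s in scans])
    intensities = np.zeros(len(scans))
    for i, spec in enumerate(scans):
        if not len(spec):
            continue
        lo_i = np.searchsorted(spec.mz, mz_target - tol, side="left")
        hi_i = np.searchsorted(spec.mz, mz_target + tol, side="right")
        if hi_i > lo_i:
            intensities[i] = spec.intensity[lo_i:hi_i].sum()
    return EIC(mz_target=mz_target, tol=tol, rts=rts, intensities=intensities,
               channel=channel)


def _merge_peaks(mz: np.ndarray, intensity: np.ndarray, tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Combine mz-sorted peaks closer than ``tol`` into intensity-weighted centroids."""
    if mz.size == 0:
        return mz, intensity
    out_mz: list[float] = []
    out_int: list[float] = []
    cur_mz = [mz[0]]
    cur_int = [intensity[0]]
    for m, h in zip(mz[1:], intensity[1:]):
        if m - cur_mz[-1] <= tol:
            cur_mz.append(m)
            cur_int.append(h)
        else:
            w = np.asarray(cur_int)
            total = w.sum()
            out_mz.append(float(np.average(cur_mz, weights=w) if total > 0 else np.mean(cur_mz)))
            out_int.append(float(total))
            cur_mz, cur_int = [m], [h]
    w = np.asarray(cur_int)
    total = w.sum()
    out_mz.append(float(np.average(cur_mz, weights=w) if total > 0 else np.mean(cur_mz)))
    out_int.append(float(total))
    return np.asarray(out_mz), np.asarray(out_int)


def spectrum_near(
    run: RawRun,
    channel: str,
    rt: float,
    n_scans: int = 3,
    merge_tol: float = 0.01,
) -> Spectrum:
    """Centroid-merged spectrum of the ``n_scans`` scans nearest ``rt``.

    Peaks within ``merge_tol`` are combined (intensity summed, m/z
    intensity-weighted). Clamps at the run edges; ``n_scans`` must be odd.
    """
    if n_scans < 1 or n_scans % 2 == 0:
        raise ValueError("n_scans must be a positive odd integer")
    scans = run.scans(channel)
    if not scans:
        raise ValueError(f"run has no {channel} scans")
    rts = np.array([s.rt for s in scans])
    order = np.argsort(np.abs(rts - rt), kind="stable")[: min(n_scans, len(scans))]
    chosen = [scans[i] for i in sorted(order)]
    if len(chosen) == 1:
        src = chosen[0]
        return Spectrum(rt=src.rt, channel=channel, mz=src.mz.copy(),
                        intensity=src.intensity.copy(), ms_level=src.ms_level,
                        collision_energy=src.collision_energy)
    all_mz = np.concatenate([s.mz for s in chosen])
    all_int = np.concatenate([s.intensity for s in chosen])
    order2 = np.argsort(all_mz, kind="stable")
    merged_mz, merged_int = _merge_peaks(all_mz[order2], all_int[order2], merge_tol)
    center_rt = float(np.median([s.rt for s in chosen]))
    return Spectrum(rt=center_rt, channel=channel, mz=merged_mz, intensity=merged_int)


def list_peaks(spec: Spectrum, min_intensity: float = 0.0) -> list[tuple[float, float]]:
    """Peaks with intensity >= ``min_intensity``, sorted by m/z."""
    mask = spec.intensity >= min_intensity
    return list(zip(spec.mz[mask].tolist(), spec.intensity[mask].tolist()))
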