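"""Synthetic AIF LC-MS run generator with known ground truth.

Emulates the data model the annotation workflow assumes: each compound's
parent adduct and all of its fragments share one Gaussian elution profile;
MS1 scans carry the parent with a binomial carbon isotope envelope (13C
natural abundance 0.0107, peak spacing 1.00336 Th) plus any declared
in-source fragments; AIF scans carry the attenuated parent and all
fragments. Multiplicative log-normal intensity noise and uniformly placed
spurious peaks with exponential intensities stress the correlation
threshold. Runs are written as standard mzML together with a feature truth
table and a matching fragment library.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.stats import binom

from .library import (
    DEFAULT_FRAGMENT_SCORE,
    DEFAULT_PARENT_SCORE,
    Library,
    LibraryFragment,
    LibraryRecord,
    adduct_polarity,
)
from .mzml import AIF, MS1, RawRun, Spectrum, write_mzml

__all__ = [
    "CompoundSpec",
    "RunSpec",
    "TruthFeature",
    "SimulatedRun",
    "simulate_run",
    "make_test_suite",
    "C13_ABUNDANCE",
    "CARBON_SPACING",
]

logger = logging.getLogger(__name__)

C13_ABUNDANCE = 0.0107
CARBON_SPACING = 1.00336

#: parent intensity in AIF scans relative to MS1 (survival of fragmentation)
AIF_PARENT_ATTENUATION = 0.3

#: isotope peaks are emitted while the envelope ratio to M+0 stays above this
ISO_RATIO_FLOOR = 1e-4

TRUTH_COLUMNS = ["feature_id", "name", "adduct", "mz", "rt_seconds",
                 "isotopologue_offset", "ion_type"]


@dataclass(frozen=True)
class CompoundSpec:
    """Ground-truth description of one simulated compound."""

    name: str
    parent_mz: float
    adduct: str = "[M+H]+"
    n_carbons: int = 20
    rt_apex: float = 300.0
    peak_sigma: float = 3.0
    parent_height: float = 1e5
    fragments: tuple[tuple[float, float], ...] = ()  # (mz, relative height in (0,1])
    in_ms1_insource: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if not self.parent_mz > 0:
            raise ValueError("parent_mz must be positive")
        if not self.peak_sigma > 0:
            raise ValueError("peak_sigma must be positive")
        for mz, rel in self.fragments + self.in_ms1_insource:
            if not (0 < rel <= 1):
                raise ValueError(f"relative height {rel} outside (0, 1]")
            if not mz > 0:
                raise ValueError("fragment mz must be positive")


@dataclass(frozen=True)
class RunSpec:
    """Acquisition and noise parameters of a simulated run."""

    rt_range: tuple[float, float] = (0.0, 600.0)
    cycle_time: float = 0.5  # seconds per MS1+AIF scan pair
    mz_range: tuple[float, float] = (50.0, 1200.0)
    noise_peak_rate: float = 0.0  # spurious peaks per scan
    noise_intensity_scale: float = 500.0  # exponential mean of spurious peaks
    intensity_noise_cv: float = 0.0  # CV of multiplicative log-normal noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cycle_time <= 0:
            raise ValueError("cycle_time must be positive")
        if self.rt_range[1] <= self.rt_range[0]:
            raise ValueError("rt_range must have positive length")


@dataclass(frozen=True)
class TruthFeature:
    feature_id: str
    name: str
    adduct: str
    mz: float
    rt: float
    isotopologue_offset: int
    ion_type: str  # parent | isotopologue | in-source fragment


@dataclass
class SimulatedRun:
    """In-memory simulation output: the run, its truth table, and library."""

    run: RawRun
    truth: list[TruthFeature]
    library: Library
    compounds: list[CompoundSpec]
    spec: RunSpec

    def truth_parents(self) -> list[TruthFeature]:
        return [t for t in self.truth if t.ion_type == "parent"]

    def write(self, outdir: str | Path, encode_channels: str = "mslevel"
              ) -> tuple[Path, Path, Path]:
        """Write mzML + truth CSV + library CSV directory; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        scans = sorted(self.run.ms1_scans + self.run.aif_scans, key=lambda s: s.rt)
        mzml_path = write_mzml(outdir / "run.mzML", scans,
                               encode_channels=encode_channels)
        truth_path = outdir / "truth.csv"
        with open(truth_path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(TRUTH_COLUMNS)
            for t in self.truth:
                writer.writerow([t.feature_id, t.name, t.adduct, repr(t.mz),
                                 repr(t.rt), t.isotopologue_offset, t.ion_type])
        from .library import write_library

        libdir = outdir / "library"
        write_library(self.library, libdir)
        return mzml_path, truth_path, libdir


def _isotope_envelope(n_carbons: int) -> np.ndarray:
    """Relative intensities of M+0..M+k for a binomial 13C envelope.

    Truncated where the ratio to M+0 falls below ``ISO_RATIO_FLOOR``.
    """
    if n_carbons <= 0:
        return np.array([1.0])
    k = np.arange(0, n_carbons + 1)
    pmf = binom.pmf(k, n_carbons, C13_ABUNDANCE)
    rel = pmf / pmf[0]
    keep = rel >= ISO_RATIO_FLOOR
    last = int(np.max(np.nonzero(keep))) if keep.any() else 0
    return rel[: last + 1]


def _gauss(t: np.ndarray | float, apex: float, sigma: float) -> np.ndarray | float:
    return np.exp(-((t - apex) ** 2) / (2.0 * sigma ** 2))


def _compound_library(compounds: list[CompoundSpec], polarity: str) -> Library:
    records = []
    for c in compounds:
        frags = [LibraryFragment(mz, DEFAULT_FRAGMENT_SCORE, "") for mz, _ in c.fragments]
        records.append(
            LibraryRecord(
                metabolite_name=c.name, adduct=c.adduct, polarity=polarity,
                parent_mz=c.parent_mz,
                parent_occurrence_score=DEFAULT_PARENT_SCORE,
                fragments=frags, source_file="simulated",
            )
        )
    return Library(records=records, polarity=polarity, source_files=["simulated"])


def simulate_run(compounds: list[CompoundSpec], spec: RunSpec) -> SimulatedRun:
    """Simulate an AIF run for the given compounds.

    MS1 and AIF scans alternate within each acquisition cycle (MS1 at the
    cycle start, AIF half a cycle later). Warns when two compounds place
    ions within 0.01 Th of each other at overlapping RT (deliberate
    ambiguity). Fully deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    _warn_overlaps(compounds)
    t0, t1 = spec.rt_range
    cycle_starts = np.arange(t0, t1, spec.cycle_time)
    # precompute per-compound static ion lists for each channel
    ms1_ions: list[list[tuple[float, float]]] = []  # (mz, relative height)
    aif_ions: list[list[tuple[float, float]]] = []
    for c in compounds:
        envelope = _isotope_envelope(c.n_carbons)
        ions1 = [(c.parent_mz + k * CARBON_SPACING, float(rel))
                 for k, rel in enumerate(envelope)]
        ions1 += [(mz, rel) for mz, rel in c.in_ms1_insource]
        ms1_ions.append(ions1)
        ions2 = [(c.parent_mz + k * CARBON_SPACING, float(rel) * AIF_PARENT_ATTENUATION)
                 for k, rel in enumerate(envelope)]
        ions2 += [(mz, rel) for mz, rel in c.fragments]
        aif_ions.append(ions2)

    ln_sigma = math.sqrt(math.log1p(spec.intensity_noise_cv ** 2))

    def _make_scan(rt: float, channel: str, ions_per_compound) -> Spectrum:
        mzs: list[float] = []
        heights: list[float] = []
        for c, ions in zip(compounds, ions_per_compound):
            profile = float(_gauss(rt, c.rt_apex, c.peak_sigma)) * c.parent_height
            if profile < 1.0:
                continue
            for mz, rel in ions:
                h = profile * rel
                if h < 1.0:
                    continue
                mzs.append(mz)
                heights.append(h)
        heights_arr = np.asarray(heights, dtype=float)
        if ln_sigma > 0 and heights_arr.size:
            # mean-one multiplicative log-normal noise
            factors = rng.lognormal(mean=-0.5 * ln_sigma ** 2, sigma=ln_sigma,
                                    size=heights_arr.size)
            heights_arr = heights_arr * factors
        n_noise = rng.poisson(spec.noise_peak_rate) if spec.noise_peak_rate > 0 else 0
        if n_noise:
            noise_mz = rng.uniform(spec.mz_range[0], spec.mz_range[1], n_noise)
            noise_h = rng.exponential(spec.noise_intensity_scale, n_noise)
            mzs.extend(noise_mz.tolist())
            heights_arr = np.concatenate([heights_arr, noise_h])
        ce = 30.0 if channel == AIF else 0.0
        return Spectrum(rt=rt, channel=channel, mz=np.asarray(mzs),
                        intensity=heights_arr, ms_level=2 if channel == AIF else 1,
                        collision_energy=ce)

    ms1_scans = [_make_scan(float(t), MS1, ms1_ions) for t in cycle_starts]
    aif_scans = [_make_scan(float(t) + spec.cycle_time / 2.0, AIF, aif_ions)
                 for t in cycle_starts]

    polarities = {adduct_polarity(c.adduct) or "positive" for c in compounds}
    polarity = polarities.pop() if len(polarities) == 1 else "positive"

    truth: list[TruthFeature] = []
    for i, c in enumerate(compounds):
        fid = f"F{i + 1:03d}"
        truth.append(TruthFeature(fid, c.name, c.adduct, c.parent_mz, c.rt_apex, 0, "parent"))
        envelope = _isotope_envelope(c.n_carbons)
        for k in range(1, min(len(envelope), 4)):
            truth.append(
                TruthFeature(f"{fid}.M{k}", c.name, c.adduct,
                             c.parent_mz + k * CARBON_SPACING, c.rt_apex, k,
                             "isotopologue")
            )
        for j, (mz, _) in enumerate(c.in_ms1_insource):
            truth.append(
                TruthFeature(f"{fid}.IS{j + 1}", c.name, c.adduct, mz, c.rt_apex,
                             0, "in-source fragment")
            )

    run = RawRun(ms1_scans=ms1_scans, aif_scans=aif_scans,
                 metadata={"simulated": True, "seed": spec.seed})
    return SimulatedRun(run=run, truth=truth,
                        library=_compound_library(compounds, polarity),
                        compounds=compounds, spec=spec)


def _warn_overlaps(compounds: list[CompoundSpec]) -> None:
    ions: list[tuple[float, float, float, str]] = []  # mz, rt, sigma, name
    for c in compounds:
        for mz in [c.parent_mz] + [m for m, _ in c.fragments]:
            ions.append((mz, c.rt_apex, c.peak_sigma, c.name))
    ions.sort()
    for (mz1, rt1, s1, n1), (mz2, rt2, s2, n2) in zip(ions, ions[1:]):
        if n1 != n2 and abs(mz1 - mz2) <= 0.01 and abs(rt1 - rt2) <= 3 * (s1 + s2):
            logger.warning(
                "ambiguous simulation: %s and %s share m/z %.4f within 0.01 Th "
                "at overlapping RT", n1, n2, mz1,
            )


# ---------------------------------------------------------------------------
# Canned scenario bundles

def _clean_compounds() -> list[CompoundSpec]:
    """25 well-separated compounds, 3 fragments each, across m/z 300-900."""
    compounds = []
    for i in range(25):
        parent = 300.0 + 25.0 * i + 0.4321  # distinct, > 0.6 Th apart
        rt = 40.0 + 20.0 * i  # 40..520 s, >> peak width apart
        frags = (
            (parent - 60.0 - 1.5 * i, 0.8),
            (parent - 130.0 - 2.0 * i, 0.5),
            (150.0 + 6.0 * i + 0.1234, 0.9),
        )
        compounds.append(
            CompoundSpec(
                name=f"CPD{i + 1:02d}", parent_mz=parent, adduct="[M+H]+",
                n_carbons=10 + 2 * i, rt_apex=rt, peak_sigma=3.0,
                parent_height=2e5, fragments=frags,
            )
        )
    return compounds


def _coeluting_compounds() -> list[CompoundSpec]:
    """Pairs sharing an RT apex and one nonspecific fragment (a head group)."""
    shared_frag = 184.0733  # phosphocholine-like head-group ion
    compounds = []
    for i in range(5):
        rt = 80.0 + 60.0 * i
        a_parent = 500.0 + 40.0 * i + 0.3
        b_parent = 640.0 + 40.0 * i + 0.7
        compounds.append(
            CompoundSpec(
                name=f"PAIR{i + 1}A", parent_mz=a_parent, n_carbons=30,
                rt_apex=rt, parent_height=2e5,
                fragments=((shared_frag, 0.9), (a_parent - 59.0, 0.6)),
            )
        )
        compounds.append(
            CompoundSpec(
                name=f"PAIR{i + 1}B", parent_mz=b_parent, n_carbons=36,
                rt_apex=rt, parent_height=1.5e5,
                fragments=((shared_frag, 0.9), (b_parent - 87.0, 0.6)),
            )
        )
    return compounds


def make_test_suite(level: str, seed: int = 20220218) -> SimulatedRun:
    """Build a canned simulation bundle: ``clean``, ``co-eluting`` or ``noisy``.

    clean: 25 well-separated compounds, no noise. co-eluting: five pairs
    sharing RT apex and one fragment m/z. noisy: the clean compounds with
    CV 0.2 multiplicative intensity noise and 50 spurious peaks per scan.
    """
    base = RunSpec(seed=seed)
    if level == "clean":
        return simulate_run(_clean_compounds(), base)
    if level == "co-eluting":
        return simulate_run(_coeluting_compounds(), base)
    if level == "noisy":
        noisy_spec = replace(base, intensity_noise_cv=0.2, noise_peak_rate=50.0)
        return simulate_run(_clean_compounds(), noisy_spec)
    raise ValueError(f"unknown test-suite level {level!r}")
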