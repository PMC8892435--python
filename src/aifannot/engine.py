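"""Candidate selection, fragment matching, scoring and ranking.

Given a feature's corrected monoisotopic m/z, candidate library records are
selected by parent m/z within a ppm tolerance (default 25 ppm, typical for
Q-ToF data); when nothing matches, the library fragment m/z values are
searched instead, treating the feature as a possible in-source fragment.

Each candidate's ions (parent + fragments) are matched against the
pseudo-MS/MS spectrum at an absolute tolerance (default 0.01 Th); ions not
found there are searched in the raw AIF spectrum, which catches fragments
shared by co-eluting compounds (e.g. phospholipid head groups) that
correlation-based deconvolution cannot attribute to a single parent.

The score of candidate i combines a mass-accuracy subscore and a
fragmentation-pattern subscore:

    S_i = w_mz * min(1/E_i, 1) + w_ma * ( sum_{ion in P} s_ion
                                          + (1/2) * sum_{ion in A} s_ion )

where E_i is the ppm error between the observed and library m/z, s_ion is
the library occurrence score of a matched ion, P the set of ions matched to
the pseudo-MS/MS spectrum and A those matched only in the AIF spectrum (down-
weighted for their lower specificity); w_mz = 1 - w_ma, default both 0.5.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .deconvolution import (
    Feature,
    IsotopologueAssignment,
    PseudoSpectrum,
    assign_isotopologue,
    build_pseudo_msms,
)
from .library import Library, LibraryRecord
from .mzml import AIF, RawRun, Spectrum, spectrum_near

__all__ = [
    "ScoringConfig",
    "IonMatch",
    "MatchResult",
    "CandidateAnnotation",
    "AnnotationResult",
    "select_candidates",
    "match_fragments",
    "score_candidate",
    "rank_candidates",
    "annotate_feature",
    "RtClassWindow",
]

logger = logging.getLogger(__name__)

DEFAULT_PPM_TOL = 25.0
DEFAULT_FRAG_TOL = 0.01
DEFAULT_AIF_DOWNWEIGHT = 2.0

PARENT_ION = "parent"


@dataclass(frozen=True)
class ScoringConfig:
    """Weights and tolerances of the annotation score."""

    w_mz: float = 0.5
    ppm_tol: float = DEFAULT_PPM_TOL
    frag_tol: float = DEFAULT_FRAG_TOL
    aif_downweight: float = DEFAULT_AIF_DOWNWEIGHT
    #: whether the parent ion's occurrence score contributes to S_ma
    count_parent_evidence: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.w_mz <= 1.0:
            raise ValueError("w_mz must lie in [0, 1]")
        if self.ppm_tol <= 0 or self.frag_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.aif_downweight < 1.0:
            raise ValueError("aif_downweight must be >= 1")

    @property
    def w_ma(self) -> float:
        return 1.0 - self.w_mz


@dataclass(frozen=True)
class IonMatch:
    """One library ion matched to one observed peak."""

    ion_label: str  # "parent" or the fragment label/index
    library_mz: float
    observed_mz: float
    occurrence_score: float


@dataclass
class MatchResult:
    """Library-ion matches split into pseudo-MS/MS (P) and AIF (A) sets.

    Each library ion appears at most once, with pseudo-MS/MS matches taking
    precedence; one observed peak may serve several library ions.
    """

    P: list[IonMatch] = field(default_factory=list)
    A: list[IonMatch] = field(default_factory=list)

    @property
    def parent_matched_in(self) -> str:
        if any(m.ion_label == PARENT_ION for m in self.P):
            return "pseudo"
        if any(m.ion_label == PARENT_ION for m in self.A):
            return "aif"
        return "none"

    @property
    def n_matched(self) -> int:
        return len(self.P) + len(self.A)


@dataclass
class CandidateAnnotation:
    """One scored library candidate for a feature."""

    record: LibraryRecord
    feature: Feature
    match_type: str  # "parent" | "in-source fragment"
    isotopologue: IsotopologueAssignment | None
    E: float  # ppm error between observed and library m/z
    matched_library_mz: float
    match: MatchResult
    S_mz: float = 0.0
    S_ma: float = 0.0
    S: float = 0.0
    rank: int = 0

    @property
    def fraction(self) -> float:
        """Matched fragments over library fragments (parent excluded)."""
        n_lib = len(self.record.fragments)
        if n_lib == 0:
            return 0.0
        n_hit = sum(1 for m in self.match.P + self.match.A if m.ion_label != PARENT_ION)
        return n_hit / n_lib


@dataclass
class AnnotationResult:
    """Everything computed for one feature: ranked candidates plus evidence."""

    feature: Feature
    candidates: list[CandidateAnnotation]
    pseudo: PseudoSpectrum | None
    isotopologue: IsotopologueAssignment | None

    @property
    def annotated(self) -> bool:
        return bool(self.candidates)

    @property
    def top(self) -> CandidateAnnotation | None:
        return self.candidates[0] if self.candidates else None


def ppm_error(observed: float, reference: float) -> float:
    return abs(observed - reference) / reference * 1e6


def select_candidates(
    mono_mz: float, lib: Library, ppm_tol: float = DEFAULT_PPM_TOL
) -> list[tuple[LibraryRecord, str, float, float]]:
    """Select library candidates for a monoisotopic m/z.

    First pass: records whose parent m/z lies within ``ppm_tol``. Only when
    that pass is empty, a second pass searches fragment m/z values (the
    feature may be an in-source fragment). Returns tuples of
    (record, match_type, ppm error E, matched library m/z).
    """
    if not mono_mz > 0:
        raise ValueError("mono_mz must be positive")
    first: list[tuple[LibraryRecord, str, float, float]] = []
    for rec in lib.records:
        e = ppm_error(mono_mz, rec.parent_mz)
        if e <= ppm_tol:
            first.append((rec, "parent", e, rec.parent_mz))
    if first:
        return first
    second: list[tuple[LibraryRecord, str, float, float]] = []
    for rec in lib.records:
        best: tuple[float, float] | None = None
        for frag in rec.fragments:
            e = ppm_error(mono_mz, frag.mz)
            if e <= ppm_tol and (best is None or e < best[0]):
                best = (e, frag.mz)
        if best is not None:
            second.append((rec, "in-source fragment", best[0], best[1]))
    return second


def _nearest_within(mz: float, peaks_mz: np.ndarray, tol: float) -> float | None:
    if peaks_mz.size == 0:
        return None
    idx = int(np.argmin(np.abs(peaks_mz - mz)))
    obs = float(peaks_mz[idx])
    return obs if abs(obs - mz) <= tol else None


def match_fragments(
    cand: LibraryRecord,
    pseudo: PseudoSpectrum,
    aif: Spectrum,
    frag_tol: float = DEFAULT_FRAG_TOL,
) -> MatchResult:
    """Match a candidate's ions to the pseudo-MS/MS, falling back to AIF.

    Every library ion (parent first, then fragments) is matched to the
    nearest pseudo-MS/MS peak within ``frag_tol`` (set P); ions unmatched
    there — or all ions when the pseudo spectrum is a fallback — are
    searched in the raw AIF spectrum (set A). P and A are disjoint by
    construction.
    """
    pseudo_mz = np.empty(0) if pseudo.is_fallback else pseudo.mz
    aif_mz = np.asarray(aif.mz, dtype=float)
    result = MatchResult()
    ions: list[tuple[str, float, float]] = [(PARENT_ION, cand.parent_mz, cand.parent_occurrence_score)]
    for i, frag in enumerate(cand.fragments):
        ions.append((frag.label or f"frag{i}", frag.mz, frag.occurrence_score))
    for label, lib_mz, score in ions:
        obs = _nearest_within(lib_mz, pseudo_mz, frag_tol)
        if obs is not None:
            result.P.append(IonMatch(label, lib_mz, obs, score))
            continue
        obs = _nearest_within(lib_mz, aif_mz, frag_tol)
        if obs is not None:
            result.A.append(IonMatch(label, lib_mz, obs, score))
    return result


def score_candidate(
    E: float,
    match: MatchResult,
    record: LibraryRecord,
    cfg: ScoringConfig = ScoringConfig(),
) -> tuple[float, float, float]:
    """Compute (S_mz, S_ma, S) for one candidate.

    S_mz = min(1/E, 1) with E in ppm (S_mz = 1 at E = 0); S_ma sums the
    occurrence scores of ions matched to the pseudo-MS/MS spectrum plus the
    downweighted scores of ions matched only in the AIF spectrum;
    S = w_mz * S_mz + w_ma * S_ma.
    """
    if E < 0:
        raise ValueError("ppm error must be >= 0")
    s_mz = 1.0 if E <= 1.0 else 1.0 / E

    def _evidence(matches: Sequence[IonMatch]) -> float:
        total = 0.0
        for m in matches:
            if m.ion_label == PARENT_ION and not cfg.count_parent_evidence:
                continue
            total += m.occurrence_score
        return total

    s_ma = _evidence(match.P) + _evidence(match.A) / cfg.aif_downweight
    s = cfg.w_mz * s_mz + cfg.w_ma * s_ma
    return s_mz, s_ma, s


def rank_candidates(cands: list[CandidateAnnotation]) -> list[CandidateAnnotation]:
    """Sort by score descending and assign ranks 1..n.

    Ties broken by lower ppm error, then more pseudo-MS/MS matches, then
    metabolite name.
    """
    ordered = sorted(
        cands,
        key=lambda c: (-c.S, c.E, -len(c.match.P), c.record.metabolite_name, c.record.adduct),
    )
    for i, cand in enumerate(ordered, start=1):
        cand.rank = i
    return ordered


@dataclass(frozen=True)
class RtClassWindow:
    """Expected retention-time window for a metabolite-class name pattern."""

    class_pattern: str
    rt_lo: float
    rt_hi: float

    def matches(self, metabolite_name: str) -> bool:
        return re.search(self.class_pattern, metabolite_name, re.IGNORECASE) is not None

    def allows(self, metabolite_name: str, rt: float) -> bool:
        if not self.matches(metabolite_name):
            return True
        return self.rt_lo <= rt <= self.rt_hi


def _apply_rt_classes(
    cands: list[tuple[LibraryRecord, str, float, float]],
    rt_classes: Sequence[RtClassWindow],
    rt: float,
) -> list[tuple[LibraryRecord, str, float, float]]:
    kept = []
    for item in cands:
        rec = item[0]
        if all(w.allows(rec.metabolite_name, rt) for w in rt_classes):
            kept.append(item)
    return kept


def annotate_feature(
    run: RawRun,
    feature: Feature,
    lib: Library,
    cfg: ScoringConfig = ScoringConfig(),
    theta: float = 0.8,
    rt_half_width: float = 10.0,
    eic_tol: float = 0.01,
    min_points: int = 5,
    r_iso: float = 0.8,
    max_k: int = 5,
    rt_classes: Sequence[RtClassWindow] = (),
    pseudo: PseudoSpectrum | None = None,
) -> AnnotationResult:
    """Run the full per-feature annotation workflow on raw AIF data.

    Pipeline: pseudo-MS/MS reconstruction -> isotopologue correction ->
    candidate selection on the monoisotopic m/z -> fragment matching with
    AIF fallback -> scoring -> ranking. A precomputed ``pseudo`` spectrum
    (e.g. loaded from MSP) replaces the reconstruction step and skips the
    isotopologue walk (its precursor is taken as monoisotopic).

    An empty candidate list means "not annotated" and is not an error.
    """
    iso: IsotopologueAssignment | None
    if pseudo is None:
        pseudo = build_pseudo_msms(
            run, feature, theta=theta, rt_half_width=rt_half_width,
            eic_tol=eic_tol, min_points=min_points,
        )
        iso = assign_isotopologue(
            run, feature, r_iso=r_iso, max_k=max_k,
            rt_half_width=rt_half_width, eic_tol=eic_tol, min_points=min_points,
        )
        mono_mz = iso.monoisotopic_mz
        aif_spec = spectrum_near(run, AIF, feature.rt, n_scans=3, merge_tol=eic_tol)
    else:
        iso = None
        mono_mz = feature.mz
        aif_spec = Spectrum(rt=feature.rt, channel=AIF, mz=np.empty(0), intensity=np.empty(0))

    selected = select_candidates(mono_mz, lib, ppm_tol=cfg.ppm_tol)
    if rt_classes:
        selected = _apply_rt_classes(selected, rt_classes, feature.rt)
    cands: list[CandidateAnnotation] = []
    for rec, match_type, e, lib_mz in selected:
        match = match_fragments(rec, pseudo, aif_spec, frag_tol=cfg.frag_tol)
        s_mz, s_ma, s = score_candidate(e, match, rec, cfg)
        cands.append(
            CandidateAnnotation(
                record=rec, feature=feature, match_type=match_type,
                isotopologue=iso, E=e, matched_library_mz=lib_mz,
                match=match, S_mz=s_mz, S_ma=s_ma, S=s,
            )
        )
    ranked = rank_candidates(cands)
    if not ranked:
        logger.info("feature %s m/z %.4f: not annotated", feature.id or "?", feature.mz)
    return AnnotationResult(feature=feature, candidates=ranked, pseudo=pseudo,
                            isotopologue=iso)
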