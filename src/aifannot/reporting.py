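"""Tabular and graphical outputs, and precision/recall evaluation.

Per feature, the ranked candidate list is written as a CSV; a combined
summary CSV collects the rank-1 annotation of every feature (with an
explicit "not annotated" row when the candidate list is empty). Optional
per-feature PDFs overlay the matched EICs and draw the pseudo-MS/MS stem
plot; the EIC panel is suppressed when annotation ran from precomputed
pseudo-spectra (MSP input), where no chromatograms exist.

Evaluation against a reference annotation set counts, per feature, the
smallest rank r <= k_max at which the reference label appears (correct),
otherwise incorrect (candidates exist) or unannotated (none). Precision and
recall follow

    precision = 100 * correct / (correct + incorrect)
    recall    = 100 * correct / (correct + unannotated)

reported half-up to one decimal. Note the recall denominator excludes
incorrectly annotated features.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

from .engine import AnnotationResult, CandidateAnnotation

__all__ = [
    "EvaluationResult",
    "write_results",
    "evaluate",
    "match_labels",
    "round_percent",
]

logger = logging.getLogger(__name__)

DEFAULT_K_MAX = 5

SUMMARY_COLUMNS = [
    "feature_id", "feature_mz", "feature_rt_seconds", "metabolite_name",
    "adduct", "ion_type", "isotopologue", "mz_matched", "mz_error_ppm",
    "n_matched_fragments", "fraction", "pseudo_msms", "S_mz", "S_ma", "S",
    "rank",
]


def round_percent(value: float, decimals: int = 1) -> float:
    """Round half-up to the given number of decimals (table presentation)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class EvaluationResult:
    """Precision/recall of automated annotations against a reference set."""

    n_features: int
    correct_by_rank: list[int]  # counts at ranks 1..k_max
    n_incorrect: int
    n_unannotated: int
    k_max: int = DEFAULT_K_MAX

    def __post_init__(self) -> None:
        if sum(self.correct_by_rank) + self.n_incorrect + self.n_unannotated != self.n_features:
            raise ValueError("correct/incorrect/unannotated counts must partition n_features")

    @property
    def n_correct(self) -> int:
        return sum(self.correct_by_rank)

    @property
    def precision(self) -> float | None:
        """Percent correct among annotated reference features; None when undefined."""
        denom = self.n_correct + self.n_incorrect
        if denom == 0:
            return None
        return round_percent(100.0 * self.n_correct / denom)

    @property
    def recall(self) -> float | None:
        denom = self.n_correct + self.n_unannotated
        if denom == 0:
            return None
        return round_percent(100.0 * self.n_correct / denom)

    def summary(self) -> str:
        prec = "NA" if self.precision is None else f"{self.precision:.1f}%"
        rec = "NA" if self.recall is None else f"{self.recall:.1f}%"
        ranks = ", ".join(
            f"rank {r}: {n}" for r, n in enumerate(self.correct_by_rank, start=1)
        )
        return (
            f"n={self.n_features} | {ranks} | incorrect: {self.n_incorrect} | "
            f"not annotated: {self.n_unannotated} | precision {prec} | recall {rec}"
        )


_ADDUCT_JUNK = re.compile(r"[\s\[\]]+")


def _normalize_name(name: str) -> str:
    return re.sub(r"\s+", " ", name.strip()).lower()


def _normalize_adduct(adduct: str) -> str:
    return _ADDUCT_JUNK.sub("", adduct).lower()


def match_labels(auto_name: str, ref_name: str,
                 auto_adduct: str = "", ref_adduct: str = "") -> bool:
    """Exact-name comparison, case-insensitive, whitespace-trimmed.

    Adduct tokens (when both sides supply one) are compared after stripping
    brackets and whitespace, so "[M+H]+" and "M+H +" agree.
    """
    if _normalize_name(auto_name) != _normalize_name(ref_name):
        return False
    if auto_adduct and ref_adduct:
        return _normalize_adduct(auto_adduct) == _normalize_adduct(ref_adduct)
    return True


@dataclass(frozen=True)
class ReferenceLabel:
    true_name: str
    true_adduct: str = ""


def evaluate(
    auto: Mapping[str, Sequence[tuple[str, str]]],
    reference: Mapping[str, ReferenceLabel],
    k_max: int = DEFAULT_K_MAX,
) -> EvaluationResult:
    """Score ranked automated annotations against reference labels.

    ``auto`` maps feature id -> ranked (name, adduct) candidates (empty
    sequence = not annotated); ``reference`` maps feature id -> truth. Every
    reference feature must appear in ``auto``. A feature is correct at the
    smallest rank r <= k_max where the reference label matches; otherwise it
    is incorrect when candidates exist, unannotated when none do.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    missing = set(reference) - set(auto)
    if missing:
        raise ValueError(f"features missing from automated results: {sorted(missing)[:5]}")
    correct_by_rank = [0] * k_max
    n_incorrect = 0
    n_unannotated = 0
    for fid in sorted(reference):
        truth = reference[fid]
        cands = list(auto[fid])
        if not cands:
            n_unannotated += 1
            continue
        hit_rank = None
        for r, (name, adduct) in enumerate(cands[:k_max], start=1):
            if match_labels(name, truth.true_name, adduct, truth.true_adduct):
                hit_rank = r
                break
        if hit_rank is None:
            n_incorrect += 1
        else:
            correct_by_rank[hit_rank - 1] += 1
    return EvaluationResult(
        n_features=len(reference),
        correct_by_rank=correct_by_rank,
        n_incorrect=n_incorrect,
        n_unannotated=n_unannotated,
        k_max=k_max,
    )


def _candidate_row(res: AnnotationResult, cand: CandidateAnnotation) -> list:
    iso = cand.isotopologue.offset if cand.isotopologue is not None else ""
    pseudo_flag = res.pseudo is not None and not res.pseudo.is_fallback
    return [
        res.feature.id, repr(res.feature.mz), repr(res.feature.rt),
        cand.record.metabolite_name, cand.record.adduct, cand.match_type,
        f"M+{iso}" if iso != "" else "",
        repr(cand.matched_library_mz), f"{cand.E:.4f}",
        cand.match.n_matched, f"{cand.fraction:.3f}",
        str(pseudo_flag), f"{cand.S_mz:.6f}", f"{cand.S_ma:.6f}",
        f"{cand.S:.6f}", cand.rank,
    ]


def write_results(
    results: Sequence[AnnotationResult],
    outdir: str | Path,
    write_pdfs: bool = False,
    run=None,
    eic_tol: float = 0.01,
    rt_half_width: float = 10.0,
) -> dict[str, Path]:
    """Write per-feature candidate CSVs and the combined rank-1 summary.

    Returns a mapping of output names to paths. With ``write_pdfs`` a PDF
    per feature is produced containing the pseudo-MS/MS stem plot and, when
    ``run`` (raw data) is given, the matched-EIC overlay; the EIC panel is
    suppressed for MSP/pseudo-spectrum input (``run is None``).
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory not writable: {outdir}: {exc}") from exc
    written: dict[str, Path] = {}
    summary_path = outdir / "annotations_rank1.csv"
    with open(summary_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SUMMARY_COLUMNS)
        for res in results:
            if res.annotated:
                writer.writerow(_candidate_row(res, res.top))
            else:
                writer.writerow(
                    [res.feature.id, repr(res.feature.mz), repr(res.feature.rt),
                     "not annotated", "", "", "", "", "", "", "",
                     str(res.pseudo is not None and not res.pseudo.is_fallback),
                     "", "", "", ""]
                )
    written["summary"] = summary_path
    all_path = outdir / "annotations_all.csv"
    with open(all_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SUMMARY_COLUMNS)
        for res in results:
            if res.annotated:
                for cand in res.candidates:
                    writer.writerow(_candidate_row(res, cand))
            else:
                writer.writerow(
                    [res.feature.id, repr(res.feature.mz), repr(res.feature.rt),
                     "not annotated", "", "", "", "", "", "", "",
                     str(res.pseudo is not None and not res.pseudo.is_fallback),
                     "", "", "", ""]
                )
    written["all"] = all_path
    for res in results:
        fid = res.feature.id or f"mz{res.feature.mz:.4f}_rt{res.feature.rt:.0f}"
        safe = re.sub(r"[^A-Za-z0-9._-]+", "_", fid)
        path = outdir / f"candidates_{safe}.csv"
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(SUMMARY_COLUMNS)
            for cand in res.candidates:
                writer.writerow(_candidate_row(res, cand))
        written[f"candidates:{fid}"] = path
        if write_pdfs:
            pdf_path = outdir / f"feature_{safe}.pdf"
            _plot_feature(res, pdf_path, run=run, eic_tol=eic_tol,
                          rt_half_width=rt_half_width)
            written[f"pdf:{fid}"] = pdf_path
    logger.info("wrote %d output files to %s", len(written), outdir)
    return written


def _plot_feature(res: AnnotationResult, path: Path, run=None,
                  eic_tol: float = 0.01, rt_half_width: float = 10.0) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .mzml import AIF, MS1, extract_eic

    with_eics = run is not None
    fig, axes = plt.subplots(2 if with_eics else 1, 1,
                             figsize=(7, 7 if with_eics else 4))
    ax_stem = axes[1] if with_eics else axes
    if with_eics:
        ax_eic = axes[0]
        feature = res.feature
        window = (feature.rt - rt_half_width, feature.rt + rt_half_width)
        feat_eic = extract_eic(run, MS1, feature.mz, tol=eic_tol, rt_window=window)
        ax_eic.plot(feat_eic.rts, feat_eic.intensities, label=f"MS1 {feature.mz:.4f}",
                    color="black", lw=2)
        if res.top is not None:
            for m in (res.top.match.P + res.top.match.A)[:8]:
                eic = extract_eic(run, AIF, m.observed_mz, tol=eic_tol, rt_window=window)
                ax_eic.plot(eic.rts, eic.intensities, alpha=0.7,
                            label=f"AIF {m.observed_mz:.4f}")
        ax_eic.set_xlabel("RT (s)")
        ax_eic.set_ylabel("intensity")
        ax_eic.legend(fontsize=7)
        ax_eic.set_title(f"feature {res.feature.id} matched EICs")
    if res.pseudo is not None and len(res.pseudo):
        mzs = [p.mz for p in res.pseudo.peaks]
        ints = [p.intensity for p in res.pseudo.peaks]
        ax_stem.vlines(mzs, 0, ints, color="steelblue")
        kind = "AIF fallback" if res.pseudo.is_fallback else "pseudo-MS/MS"
        ax_stem.set_title(f"{kind} ({len(mzs)} peaks)")
    ax_stem.set_xlabel("m/z")
    ax_stem.set_ylabel("intensity")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
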