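"""Benchmark metrics: RMSE, the alignment-length baseline, error categories.

The baseline estimator ("BAMself"-style) takes whatever the aligner says:
the length of the read segment aligned across the reference repeat
interval, divided by the unit length and rounded.  It inherits the net
insertion bias of the raw reads, which is exactly why a model-based counter
is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .repeat_spec import LocusReference

__all__ = [
    "CATEGORY_LABELS",
    "EvaluationResult",
    "rmse",
    "bamself_estimate",
    "bamself_from_cigar",
    "categorize_errors",
]

#: Prediction-error bins (estimate minus truth).
CATEGORY_LABELS = ("<-3", "-3", "-2", "-1", "0", "1", "2", "3", ">3")


def rmse(true_counts: Sequence[float], est_counts: Sequence[float]) -> float:
    """Root mean square error between paired count vectors."""
    t = np.asarray(true_counts, dtype=float)
    e = np.asarray(est_counts, dtype=float)
    if t.shape != e.shape or t.size == 0:
        raise ValueError("count vectors must have equal nonzero length")
    return float(np.sqrt(np.mean((t - e) ** 2)))


def categorize_errors(
    true_counts: Sequence[float], est_counts: Sequence[float]
) -> dict[str, int]:
    """Nine-bin histogram of prediction errors (estimate minus truth)."""
    t = np.asarray(true_counts, dtype=float)
    e = np.asarray(est_counts, dtype=float)
    if t.shape != e.shape:
        raise ValueError("count vectors must have equal length")
    diffs = np.rint(e - t).astype(int)
    bins = dict.fromkeys(CATEGORY_LABELS, 0)
    for d in diffs:
        if d < -3:
            bins["<-3"] += 1
        elif d > 3:
            bins[">3"] += 1
        else:
            bins[str(d)] += 1
    return bins


def bamself_from_cigar(
    cigar: Sequence[tuple[int, int]],
    ref_start: int,
    tract_start: int,
    tract_end: int,
    unit_length: int,
) -> int | None:
    """Baseline count from an alignment's CIGAR.

    ``cigar`` uses pysam operation codes ((op, length); 0=M, 1=I, 2=D,
    4=S, 7= =, 8=X); ``ref_start`` is the 0-based reference position of the
    first aligned base, and ``tract_start``/``tract_end`` the 0-based
    half-open reference repeat interval.  Counts the read bases consumed
    while the reference cursor is inside the interval (insertions included),
    then divides by the unit length and rounds.  Returns None when the
    alignment does not overlap the interval.
    """
    consumes_read = {0, 1, 4, 7, 8}
    consumes_ref = {0, 2, 7, 8}
    ref = ref_start
    span = 0
    overlapped = False
    for op, length in cigar:
        in_read = op in consumes_read
        in_ref = op in consumes_ref
        if not in_read and not in_ref:
            continue
        if in_ref:
            lo = max(ref, tract_start)
            hi = min(ref + length, tract_end)
            if lo < hi:
                overlapped = True
                if in_read:
                    span += hi - lo
            ref += length
        else:
            # Insertions at or within one unit of the tract edges count as
            # part of the repeat span: a repeat-run insertion is placement-
            # ambiguous under periodicity and aligners may park it a few
            # bases outside the annotated interval.  Raw long reads are
            # net-inserted, which gives this baseline its characteristic
            # overestimate.
            lo = tract_start - unit_length
            hi = tract_end + unit_length
            if lo <= ref <= hi and op != 4:
                overlapped = True
                span += length
    if not overlapped:
        return None
    return int(np.floor(span / unit_length + 0.5))


def bamself_estimate(read: str, locus: LocusReference) -> int | None:
    """Baseline count for one read: raw aligned repeat span over unit length.

    The internal stand-in for a BAM-derived estimate: the read is localized
    against the locus (split-and-align with whole-read fallback, exactly as
    the genotyping pipeline does) and the *uncorrected* repeat-region span
    is divided by the unit length and rounded.  Because raw long reads are
    net-inserted (insertion rate above deletion rate), this length-based
    estimate systematically overestimates the repeat count — the behavior
    that motivates model-based counting.  Returns None for reads that
    cannot be localized.  Counts from an externally supplied BAM go through
    :func:`bamself_from_cigar` instead.
    """
    from .read_localization import RejectedRead, localize_read

    result = localize_read("baseline", read, locus)
    if isinstance(result, RejectedRead):
        return None
    span = result.tract_end - result.tract_start
    return int(np.floor(span / locus.spec.unit_length + 0.5))


@dataclass
class EvaluationResult:
    """Per-cohort accuracy summary for one estimator."""

    rmse_normal: float
    rmse_pathogenic: float
    error_categories: dict[str, int]
    per_participant: list[dict[str, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "rmse_normal": self.rmse_normal,
            "rmse_pathogenic": self.rmse_pathogenic,
            "error_categories": dict(self.error_categories),
            "per_participant": list(self.per_participant),
        }


def evaluate_calls(
    truths: Sequence[tuple[int, int]],
    calls: Sequence[tuple[int, int]],
    ids: Sequence[str] | None = None,
) -> EvaluationResult:
    """Pair (normal, pathogenic) truths with sorted calls and summarise.

    The smaller called allele is scored against the smaller true allele.
    """
    if len(truths) != len(calls):
        raise ValueError("truths and calls must pair up")
    t_norm, t_path, e_norm, e_path = [], [], [], []
    table = []
    for k, ((tc_i, tc_j), call) in enumerate(zip(truths, calls)):
        lo_t, hi_t = sorted((tc_i, tc_j))
        lo_e, hi_e = sorted(call)
        t_norm.append(lo_t)
        t_path.append(hi_t)
        e_norm.append(lo_e)
        e_path.append(hi_e)
        table.append(
            {
                "participant": ids[k] if ids else str(k),
                "true_normal": lo_t,
                "true_pathogenic": hi_t,
                "est_normal": lo_e,
                "est_pathogenic": hi_e,
            }
        )
    cats = categorize_errors(t_norm + t_path, e_norm + e_path)
    return EvaluationResult(
        rmse_normal=rmse(t_norm, e_norm),
        rmse_pathogenic=rmse(t_path, e_path),
        error_categories=cats,
        per_participant=table,
    )
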