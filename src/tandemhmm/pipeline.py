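"""End-to-end genotyping: localize, correct, decode, tally, peak-call.

:func:`genotype_sample` runs the per-read stages over a read set and
reduces the per-read repeat counts to an allele call.
:func:`run_benchmark` wraps the simulator around it and scores both the
model-based counter and the alignment-length baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .error_correction import AlignParams, correct_read_region
from .evaluation import EvaluationResult, bamself_estimate, evaluate_calls
from .hmm_engine import HmmModel, build_model, repeat_count_from_path, viterbi
from .peak_calling import AlleleCall, NoInformativeReadsError, call_from_counts
from .read_localization import LocalizedRead, RejectedRead, localize_read
from .repeat_spec import ErrorProfile, LocusReference
from .simulator import (
    SimConfig,
    SimulatedParticipant,
    simulate_participant_pcr,
    simulate_participant_random,
)

__all__ = ["GenotypeOptions", "GenotypeResult", "genotype_sample", "run_benchmark"]

logger = logging.getLogger(__name__)


#: Correction scoring used by the genotyping pipeline.  The read-gap
#: penalty is −2 rather than the aligner's illustrative standalone default
#: of −10: with a trinucleotide unit, a −10 read gap makes excising the
#: remaining two bases of a unit (2 × −1 template gaps) cheaper than
#: honouring a true deletion, so the optimal alignment silently removes one
#: whole unit per sequencing deletion.  At −2 deletions survive as holes in
#: the corrected read, where the decoder's deletion states count them,
#: while insertion stripping (the purpose of the correction) is unaffected.
PIPELINE_ALIGN_PARAMS = AlignParams(gap_in_read=-2.0)


@dataclass(frozen=True)
class GenotypeOptions:
    """Tunable parameters of the genotyping pipeline (defaults as documented)."""

    correct_errors: bool = True
    identity_threshold: float = 0.8
    min_count: int = 5
    min_reads: int = 3
    n_range: tuple[int, int] = (3, 7)
    n_restarts: int = 20
    second_peak_ratio: float = 0.8
    align_params: AlignParams = field(default_factory=lambda: PIPELINE_ALIGN_PARAMS)
    seed: int = 42


@dataclass
class GenotypeResult:
    """Allele call plus per-read and per-stage diagnostics for one sample."""

    sample_id: str
    call: AlleleCall | None
    per_read_counts: list[int]
    rejections: dict[str, int]
    n_input_reads: int
    options: GenotypeOptions

    @property
    def n_accepted(self) -> int:
        return len(self.per_read_counts)

    def to_dict(self) -> dict:
        call = None
        if self.call is not None:
            call = {
                "allele1": self.call.allele1,
                "allele2": self.call.allele2,
                "support1": self.call.support1,
                "support2": self.call.support2,
                "zygosity": self.call.zygosity,
            }
        return {
            "sample_id": self.sample_id,
            "call": call,
            "n_input_reads": self.n_input_reads,
            "n_accepted": self.n_accepted,
            "rejections": dict(self.rejections),
            "per_read_counts": list(self.per_read_counts),
        }


def count_read(
    localized: LocalizedRead,
    model: HmmModel,
    pattern: str,
    options: GenotypeOptions,
) -> int:
    """Per-read repeat count: optional correction, then Viterbi decoding."""
    tract = localized.tract
    if options.correct_errors and tract:
        tract = correct_read_region(tract, pattern, options.align_params)
    prepared = localized.prepared_with(tract)
    path = viterbi(prepared, model)
    return repeat_count_from_path(path, model.unit_length)


def _effective_min_reads(options: GenotypeOptions, n_counts: int) -> int:
    """Coverage-scaled histogram-bin support threshold.

    At depth, stray bins of a few reads (localization glitches, error
    bursts) are noise, so the minimum grows with the number of informative
    reads: 2% of them, floored at ``options.min_reads``.
    """
    return max(options.min_reads, int(np.ceil(0.02 * n_counts)))


def genotype_sample(
    reads: Iterable[tuple[str, str]],
    locus: LocusReference,
    profile: ErrorProfile | None = None,
    options: GenotypeOptions | None = None,
    sample_id: str = "sample",
) -> GenotypeResult:
    """Genotype one sample from an iterable of ``(read_id, sequence)`` pairs.

    Deterministic for a fixed seed and input order.  A sample in which no
    read survives localization and filtering gets ``call=None`` together
    with the per-reason rejection tallies.
    """
    profile = profile or ErrorProfile()
    options = options or GenotypeOptions()
    model = build_model(locus.spec, profile)
    counts: list[int] = []
    rejections: dict[str, int] = {}
    n_input = 0
    for read_id, sequence in reads:
        n_input += 1
        if not sequence:
            rejections["no_tract"] = rejections.get("no_tract", 0) + 1
            continue
        loc = localize_read(
            read_id, sequence, locus, identity_threshold=options.identity_threshold
        )
        if isinstance(loc, RejectedRead):
            rejections[loc.reason] = rejections.get(loc.reason, 0) + 1
            continue
        counts.append(count_read(loc, model, locus.spec.pattern, options))
    call: AlleleCall | None = None
    if counts:
        try:
            call = call_from_counts(
                counts,
                min_count=options.min_count,
                min_reads=_effective_min_reads(options, len(counts)),
                n_range=options.n_range,
                n_restarts=options.n_restarts,
                second_peak_ratio=options.second_peak_ratio,
                seed=options.seed,
            )
        except NoInformativeReadsError:
            logger.warning("%s: all %d per-read counts filtered out", sample_id, len(counts))
    else:
        logger.warning("%s: zero accepted reads (%s)", sample_id, rejections)
    return GenotypeResult(
        sample_id=sample_id,
        call=call,
        per_read_counts=counts,
        rejections=rejections,
        n_input_reads=n_input,
        options=options,
    )


def _genotype_participant(
    part: SimulatedParticipant,
    locus: LocusReference,
    profile: ErrorProfile,
    options: GenotypeOptions,
) -> GenotypeResult:
    return genotype_sample(
        ((r.read_id, r.sequence) for r in part.reads),
        locus,
        profile,
        options,
        sample_id=part.participant_id,
    )


def _baseline_call(
    part: SimulatedParticipant, locus: LocusReference, options: GenotypeOptions
) -> tuple[int, int] | None:
    counts = [
        c
        for r in part.reads
        if (c := bamself_estimate(r.sequence, locus)) is not None
    ]
    if not counts:
        return None
    try:
        call = call_from_counts(
            counts,
            min_count=options.min_count,
            min_reads=_effective_min_reads(options, len(counts)),
            n_range=options.n_range,
            n_restarts=options.n_restarts,
            second_peak_ratio=options.second_peak_ratio,
            seed=options.seed,
        )
    except NoInformativeReadsError:
        return None
    return call.alleles


def run_benchmark(
    config: SimConfig,
    coverages: Sequence[int],
    seed: int = 42,
    protocol: str = "random",
    with_baseline: bool = True,
    options: GenotypeOptions | None = None,
) -> dict[int, dict[str, EvaluationResult]]:
    """Simulate, genotype and score cohorts at each coverage level.

    Returns ``{coverage: {"hmm": EvaluationResult, "baseline": ...}}``.
    Participants whose call fails are scored as (0, 0), which penalises the
    estimator rather than silently dropping the sample.
    """
    options = options or GenotypeOptions()
    simulate = (
        simulate_participant_random if protocol == "random" else simulate_participant_pcr
    )
    results: dict[int, dict[str, EvaluationResult]] = {}
    for cov in coverages:
        rng = np.random.default_rng(seed + cov)
        cov_config = replace(config, coverage=cov)
        truths: list[tuple[int, int]] = []
        hmm_calls: list[tuple[int, int]] = []
        base_calls: list[tuple[int, int]] = []
        ids: list[str] = []
        for p in range(config.n_participants):
            part = simulate(cov_config, rng, participant_id=f"cov{cov}_p{p}")
            truths.append((part.c_i, part.c_j))
            ids.append(part.participant_id)
            res = _genotype_participant(part, config.locus, config.profile, options)
            hmm_calls.append(res.call.alleles if res.call else (0, 0))
            if with_baseline:
                base = _baseline_call(part, config.locus, options)
                base_calls.append(base if base else (0, 0))
        entry = {"hmm": evaluate_calls(truths, hmm_calls, ids)}
        if with_baseline:
            entry["baseline"] = evaluate_calls(truths, base_calls, ids)
        results[cov] = entry
    return results
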