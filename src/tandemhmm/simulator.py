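"""Long-read simulation over a repeat locus, with truth tracking.

Two protocols are implemented.  The *random-read* protocol draws, per
participant, a normal and an expanded allele count, rebuilds the locus with
each allele, and emits reads whose flank lengths are drawn from a normal
distribution around half the locus padding — with the longer allele's
flanks shortened by half the extra tract length so both alleles produce
reads of similar total length.  The *PCR amplicon* protocol instead clips
each allele sequence at a fixed primer pair, so every read spans the same
region.  Both mutate reads with independent per-base insertion / deletion /
substitution events (PacBio defaults 11% / 2% / 2%) and allocate coverage
between alleles inversely to allele length: the allele with count ``c_i``
receives ``c_j / (c_i + c_j) * cov`` reads, i.e. longer templates yield
fewer reads.  PCR slippage/stutter is deliberately not modelled.

The packaged reference locus is synthetic: seeded random flanks around a
14-unit CAG tract with a primer pair embedded such that the
primer-to-primer product in the reference is 762 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .repeat_spec import ErrorProfile, LocusReference, RepeatSpec, reverse_complement

__all__ = [
    "SimConfig",
    "SimulatedRead",
    "SimulatedParticipant",
    "synthetic_locus",
    "mutate_sequence",
    "simulate_participant_random",
    "simulate_participant_pcr",
    "allele_read_allocation",
    "DEFAULT_FWD_PRIMER",
    "DEFAULT_REV_PRIMER",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Primer pair for the packaged amplicon protocol (product 762 bp in the
#: reference fixture).
DEFAULT_FWD_PRIMER = "CCCACCCACTACTCCCATTT"
DEFAULT_REV_PRIMER = "CCAGAGTTTCCGTGATGCTG"


def synthetic_locus(
    pattern: str = "CAG",
    reference_units: int = 14,
    flank: int = 1600,
    product_size: int = 762,
    gene_name: str = "ATN1",
    seed: int = 20170718,
) -> LocusReference:
    """Build the packaged synthetic reference locus.

    Deterministic random flanks (fixed seed — this is a fixture, not a
    simulation draw) surround a ``reference_units`` tract, with the default
    primer pair embedded symmetrically so the primer-to-primer product has
    ``product_size`` bp in the reference.  Coordinates in the returned spec
    are 1-based inclusive within the returned sequence.
    """
    rng = np.random.default_rng(seed)
    tract = pattern * reference_units
    fwd, rev = DEFAULT_FWD_PRIMER, DEFAULT_REV_PRIMER
    pad = product_size - len(tract) - len(fwd) - len(rev)
    if pad < 0:
        raise ValueError("product_size too small for tract and primers")
    gap_up = pad // 2
    gap_down = pad - gap_up

    forbidden = (pattern * 2, reverse_complement(pattern * 2))

    def rand_seq(n: int) -> str:
        # flanks must not contain two consecutive repeat units (either
        # strand) so tract detection in the fixture is unambiguous; single
        # unit occurrences are harmless and left in place
        s = list(bytes(rng.choice(_BASES, size=n)).decode())
        changed = True
        while changed:
            changed = False
            text = "".join(s)
            for bad in forbidden:
                at = text.find(bad)
                while at >= 0:
                    mid = at + len(bad) // 2
                    old = s[mid]
                    while s[mid] == old:
                        s[mid] = chr(rng.choice(_BASES))
                    changed = True
                    at = text.find(bad, at + 1)
            if changed:
                continue
        return "".join(s)

    upstream = rand_seq(flank - len(fwd) - gap_up) + fwd + rand_seq(gap_up)
    downstream = rand_seq(gap_down) + reverse_complement(rev) + rand_seq(
        flank - len(rev) - gap_down
    )
    sequence = upstream + tract + downstream
    spec = RepeatSpec(
        gene_name=gene_name,
        chrom="locus",
        start=len(upstream) + 1,
        end=len(upstream) + len(tract),
        pattern=pattern,
    )
    return LocusReference(spec=spec, sequence=sequence)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated cohort.

    Defaults follow the expanded-CAG benchmark: normal alleles uniform in
    6–35, pathogenic in 49–88, PacBio error rates, and locus padding
    ``updown_size = min(max_repeat * 25, 1500)``.
    """

    locus: LocusReference = field(default_factory=synthetic_locus)
    normal_range: tuple[int, int] = (6, 35)
    pathogenic_range: tuple[int, int] = (49, 88)
    coverage: int = 100
    profile: ErrorProfile = field(default_factory=ErrorProfile)
    flank_sd: float = 10.0
    n_participants: int = 100

    def __post_init__(self) -> None:
        for rng_ in (self.normal_range, self.pathogenic_range):
            if rng_[0] > rng_[1] or rng_[0] < 1:
                raise ValueError(f"invalid repeat range {rng_}")
        if self.coverage < 1:
            raise ValueError("coverage must be >= 1")

    @property
    def max_repeat(self) -> int:
        return max(self.normal_range[1], self.pathogenic_range[1])

    @property
    def updown_size(self) -> int:
        return min(self.max_repeat * 25, 1500)


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    tract_start: int  # 0-based half-open, in read coordinates
    tract_end: int
    true_count: int
    allele: str  # "normal" | "pathogenic" | "allele1" | "allele2"


@dataclass(frozen=True)
class SimulatedParticipant:
    participant_id: str
    c_i: int  # smaller (normal) allele count
    c_j: int  # larger (pathogenic) allele count
    reads: tuple[SimulatedRead, ...]


class MutationRecord:
    """Event log from one mutate_sequence call (for truth tracking)."""

    __slots__ = ("n_insertions", "n_deletions", "n_substitutions")

    def __init__(self, n_ins: int, n_del: int, n_sub: int) -> None:
        self.n_insertions = n_ins
        self.n_deletions = n_del
        self.n_substitutions = n_sub


def mutate_sequence(
    seq: str, profile: ErrorProfile, rng: np.random.Generator
) -> tuple[str, MutationRecord]:
    """Apply independent per-base errors to ``seq``.

    Each base is deleted with probability ``del_rate``, else substituted to
    a different uniform base with probability ``sub_rate``; independently a
    uniform random base is inserted after each position with probability
    ``ins_rate``.  Expected length ratio is ``1 + ins_rate - del_rate``.
    """
    if not seq:
        raise ValueError("empty sequence")
    i, d, s = profile.ins_rate, profile.del_rate, profile.sub_rate
    if i >= 1.0 or d + s >= 1.0:
        raise ValueError("error rates too large for the per-base event model")
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    n = len(arr)
    u = rng.random(n)
    deleted = u < d
    substituted = (~deleted) & (u < d + s)
    inserted = rng.random(n) < i
    # Substitution: shift to one of the three other bases.
    base_idx = np.searchsorted(_BASES, arr)
    sub_pos = np.nonzero(substituted)[0]
    new_idx = (base_idx[sub_pos] + rng.integers(1, 4, size=len(sub_pos))) % 4
    out = arr.copy()
    out[sub_pos] = _BASES[new_idx]
    ins_pos = np.nonzero(inserted)[0]
    ins_base = _BASES[rng.integers(0, 4, size=len(ins_pos))]
    pieces: list[np.ndarray] = []
    keep = ~deleted
    prev = 0
    for p, b in zip(ins_pos, ins_base):
        seg = out[prev : p + 1][keep[prev : p + 1]]
        pieces.append(seg)
        pieces.append(np.array([b], dtype=np.uint8))
        prev = p + 1
    pieces.append(out[prev:][keep[prev:]])
    mutated = np.concatenate(pieces) if pieces else out[keep]
    record = MutationRecord(int(inserted.sum()), int(deleted.sum()), int(substituted.sum()))
    return bytes(mutated).decode(), record


def allele_read_allocation(c_i: int, c_j: int, cov: int) -> tuple[int, int]:
    """Reads for the (c_i, c_j) alleles: longer repeats get fewer reads.

    The longer allele gets ``round(c_i / (c_i + c_j) * cov)`` reads and the
    shorter allele the remainder, preserving total coverage.
    """
    if c_i > c_j:
        n_j, n_i = allele_read_allocation(c_j, c_i, cov)
        return n_i, n_j
    n_j = int(np.floor(c_i / (c_i + c_j) * cov + 0.5))
    return cov - n_j, n_j


def _allele_locus(locus: LocusReference, count: int) -> tuple[str, int, int]:
    """Locus sequence carrying ``count`` repeat units; returns tract bounds.

    Because inserting units of the same motif at any unit boundary of a pure
    tract produces the identical string, the tract is set to ``count`` units
    directly (this also covers counts below the reference count).
    """
    spec = locus.spec
    up = locus.upstream
    down = locus.downstream
    tract = spec.pattern * count
    return up + tract + down, len(up), len(up) + len(tract)


def _simulate_allele_read(
    allele_seq: str,
    t_start: int,
    t_end: int,
    up_len: int,
    down_len: int,
    profile: ErrorProfile,
    rng: np.random.Generator,
) -> tuple[str, int, int]:
    """One read: flank tail + tract + flank head, each mutated separately.

    Mutating the three parts separately is equivalent to mutating their
    concatenation under the per-base event model and keeps the truth tract
    bounds exact in read coordinates.
    """
    up = allele_seq[max(0, t_start - up_len) : t_start]
    tract = allele_seq[t_start:t_end]
    down = allele_seq[t_end : t_end + down_len]
    m_up, _ = mutate_sequence(up, profile, rng) if up else ("", None)
    m_tract, _ = mutate_sequence(tract, profile, rng)
    m_down, _ = mutate_sequence(down, profile, rng) if down else ("", None)
    return m_up + m_tract + m_down, len(m_up), len(m_up) + len(m_tract)


def _draw_flank(mean: float, sd: float, min_flank: int, limit: int,
                rng: np.random.Generator) -> int:
    """Normal flank-length draw, redrawn (bounded) if below the minimum."""
    for _ in range(100):
        v = int(round(rng.normal(mean, sd)))
        if min_flank <= v <= limit:
            return v
    return max(min_flank, min(limit, int(mean)))


def simulate_participant_random(
    config: SimConfig,
    rng: np.random.Generator,
    participant_id: str = "p0",
) -> SimulatedParticipant:
    """Random start/end protocol for one participant.

    Flank lengths are N(L, flank_sd) with L = updown_size / 2 for the
    shorter allele and L minus half the extra tract length for the longer
    one.
    """
    lo_n, hi_n = config.normal_range
    lo_p, hi_p = config.pathogenic_range
    c_i = int(rng.integers(lo_n, hi_n + 1))
    c_j = int(rng.integers(lo_p, hi_p + 1))
    return _simulate_reads(config, c_i, c_j, rng, participant_id)


def _simulate_reads(
    config: SimConfig,
    c_i: int,
    c_j: int,
    rng: np.random.Generator,
    participant_id: str,
    labels: tuple[str, str] = ("normal", "pathogenic"),
) -> SimulatedParticipant:
    spec = config.locus.spec
    unit = spec.unit_length
    n_i, n_j = allele_read_allocation(c_i, c_j, config.coverage)
    half = config.updown_size / 2.0
    reads: list[SimulatedRead] = []
    for count, n_reads, label, mean_flank in (
        (c_i, n_i, labels[0], half),
        (c_j, n_j, labels[1], half - abs(c_i - c_j) * unit / 2.0),
    ):
        allele_seq, t_start, t_end = _allele_locus(config.locus, count)
        mean_flank = max(mean_flank, spec.min_flank + 3.0 * config.flank_sd)
        for r in range(n_reads):
            up_len = _draw_flank(mean_flank, config.flank_sd, spec.min_flank,
                                 t_start, rng)
            down_len = _draw_flank(mean_flank, config.flank_sd, spec.min_flank,
                                   len(allele_seq) - t_end, rng)
            seq, rs, re = _simulate_allele_read(
                allele_seq, t_start, t_end, up_len, down_len, config.profile, rng
            )
            reads.append(
                SimulatedRead(
                    read_id=f"{participant_id}_{label}_{r}",
                    sequence=seq,
                    tract_start=rs,
                    tract_end=re,
                    true_count=count,
                    allele=label,
                )
            )
    return SimulatedParticipant(
        participant_id=participant_id, c_i=c_i, c_j=c_j, reads=tuple(reads)
    )


def simulate_participant_pcr(
    config: SimConfig,
    rng: np.random.Generator,
    fwd_primer: str = DEFAULT_FWD_PRIMER,
    rev_primer: str = DEFAULT_REV_PRIMER,
    participant_id: str = "p0",
) -> SimulatedParticipant:
    """PCR amplicon protocol: fixed primer-to-primer reads.

    The amplicon is the primer-to-primer segment of each allele sequence
    (the reverse primer is located as its reverse complement on the forward
    strand); mutation and coverage allocation are identical to the random
    protocol.
    """
    lo_n, hi_n = config.normal_range
    lo_p, hi_p = config.pathogenic_range
    c_i = int(rng.integers(lo_n, hi_n + 1))
    c_j = int(rng.integers(lo_p, hi_p + 1))
    spec = config.locus.spec
    up = config.locus.upstream
    down = config.locus.downstream
    fwd_at = up.find(fwd_primer.upper())
    rev_rc = reverse_complement(rev_primer.upper())
    rev_at = down.find(rev_rc)
    if fwd_at < 0:
        raise ValueError("forward primer not found in the upstream flank")
    if rev_at < 0:
        raise ValueError("reverse primer not found in the downstream flank")
    n_i, n_j = allele_read_allocation(c_i, c_j, config.coverage)
    reads: list[SimulatedRead] = []
    for count, n_reads, label in ((c_i, n_i, "normal"), (c_j, n_j, "pathogenic")):
        allele_seq, t_start, t_end = _allele_locus(config.locus, count)
        amp_start = fwd_at
        amp_end = t_end + rev_at + len(rev_rc)
        up_len = t_start - amp_start
        down_len = amp_end - t_end
        for r in range(n_reads):
            seq, rs, re = _simulate_allele_read(
                allele_seq, t_start, t_end, up_len, down_len, config.profile, rng
            )
            reads.append(
                SimulatedRead(
                    read_id=f"{participant_id}_{label}_{r}",
                    sequence=seq,
                    tract_start=rs,
                    tract_end=re,
                    true_count=count,
                    allele=label,
                )
            )
    return SimulatedParticipant(
        participant_id=participant_id, c_i=c_i, c_j=c_j, reads=tuple(reads)
    )


def simulate_similar_alleles(
    config: SimConfig,
    difference: int,
    rng: np.random.Generator,
    participant_id: str = "p0",
) -> SimulatedParticipant:
    """Heterozygote whose alleles differ by exactly ``difference`` repeats.

    The base allele is drawn uniformly across the full study range (normal
    minimum up to pathogenic maximum minus the difference); used to probe
    how the peak caller behaves when the two alleles are nearly identical.
    """
    lo = config.normal_range[0]
    hi = max(config.normal_range[1], config.pathogenic_range[1]) - difference
    c_i = int(rng.integers(lo, hi + 1))
    c_j = c_i + difference
    return _simulate_reads(
        config, c_i, c_j, rng, participant_id, labels=("allele1", "allele2")
    )
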