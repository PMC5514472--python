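"""Locate the repeat tract in each long read and anchor it to the locus.

The split-and-align strategy: a rotation-aware sliding-window scorer finds
candidate repeat tracts directly in the read; the flanking subsequences on
either side of the best tract are then anchored to the locus reference by
infix (semi-global) alignment.  Reads whose flanks anchor in the correct
order with high identity are accepted; the rest fall back to whole-read
alignment against the locus, and reads that still cannot be placed — or
whose flanks are shorter than the minimum (default 18 bp) — are rejected
with a reason code.  Reverse-strand reads are detected and
reverse-complemented before any downstream stage.

Accepted reads carry a ``prepared`` segment — a short flank tail, three Ns,
the tract, three more Ns, and the other flank tail — in which the N
separators force the decoder's NonRepeat state at the tract boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import edlib
import numpy as np

from .repeat_spec import LocusReference, RepeatSpec, canonical_rotations, reverse_complement

__all__ = [
    "TractCandidate",
    "FlankAnchors",
    "LocalizedRead",
    "RejectedRead",
    "find_tandem_tracts",
    "align_flanks",
    "localize_read",
]

#: Number of N separator bases inserted on each side of the tract (one full
#: trinucleotide unit of symbols no repeat state can emit).
N_SEPARATOR = "NNN"

#: Flank tail length carried into the prepared segment on each side.  Tract
#: bases eroded by boundary errors during detection land in the tails,
#: where the decoder still counts them; flank bases simply decode as
#: NonRepeat.
FLANK_TAIL = 15

#: Outward padding (in units) applied to the detected tract interval.
#: Boundary windows dense in sequencing errors fail the detection
#: threshold, eroding the tract by several bases; padding puts them back
#: inside the corrected region, where the decoder counts them, while
#: genuine flank bases simply decode as NonRepeat.
TRACT_PAD_UNITS = 4

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class TractCandidate:
    """A candidate repeat tract: 0-based half-open offsets into the read."""

    start: int
    end: int
    approx_units: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FlankAnchors:
    """Placement of the two flanks in the reference window (half-open)."""

    up_start: int
    up_end: int
    up_identity: float
    down_start: int
    down_end: int
    down_identity: float

    @property
    def ordered(self) -> bool:
        # Small slack tolerates boundary slop from tract detection.
        return self.up_end <= self.down_start + 5

    @property
    def min_identity(self) -> float:
        return min(self.up_identity, self.down_identity)


@dataclass(frozen=True)
class LocalizedRead:
    """A read with its repeat tract identified, oriented to the forward strand.

    ``tract_start``/``tract_end`` are the detected bounds.  ``pad`` bases of
    raw flank on each side are kept contiguous with the tract in the
    prepared segment (inside the N separators) so that boundary-eroded
    tract bases are still decoded in-run; the pads are never themselves
    error-corrected, since correcting non-repeat sequence against a perfect
    template strips the non-conforming bases and launders flank into
    phantom repeat units.
    """

    read_id: str
    sequence: str
    tract_start: int
    tract_end: int
    anchored: bool
    strand: str = "+"
    pad: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.tract_start < self.tract_end <= len(self.sequence):
            raise ValueError("tract bounds outside read")

    @property
    def upstream_len(self) -> int:
        return self.tract_start

    @property
    def downstream_len(self) -> int:
        return len(self.sequence) - self.tract_end

    @property
    def tract(self) -> str:
        return self.sequence[self.tract_start : self.tract_end]

    @property
    def prepared(self) -> str:
        return self.prepared_with()

    def prepared_with(self, tract_override: str | None = None) -> str:
        """N-separated decoder input, optionally with a corrected tract."""
        tract = self.tract if tract_override is None else tract_override
        pad_from = max(0, self.tract_start - self.pad)
        pad_to = min(len(self.sequence), self.tract_end + self.pad)
        pad_l = self.sequence[pad_from : self.tract_start]
        pad_r = self.sequence[self.tract_end : pad_to]
        up_tail = self.sequence[max(0, pad_from - FLANK_TAIL) : pad_from]
        down_head = self.sequence[pad_to : pad_to + FLANK_TAIL]
        return up_tail + N_SEPARATOR + pad_l + tract + pad_r + N_SEPARATOR + down_head


@dataclass(frozen=True)
class RejectedRead:
    """A discarded read and why: no_tract, short_flank, low_identity, unaligned."""

    read_id: str
    reason: str


def _accept_table(spec: RepeatSpec, rotation: str, offset: int) -> np.ndarray:
    """(window_len, 4) acceptance per position for one rotation of the unit.

    Mixed positions accept every base carried by their weight distribution,
    so mixed-pattern tracts are not penalised during detection.
    """
    e = spec.unit_length
    table = np.zeros((2 * e, 4), dtype=bool)
    for w in range(2 * e):
        unit_pos = 1 + (offset + w) % e
        for base in spec.unit_distribution(unit_pos):
            table[w, _BASE_INDEX[base]] = True
    return table


def find_tandem_tracts(
    read: str,
    spec: RepeatSpec,
    min_fraction: float = 0.8,
    merge_gap: int | None = None,
) -> list[TractCandidate]:
    """Candidate repeat tracts from a rotation-aware sliding window.

    A window of two repeat units starting at each read offset is scored
    against every rotation of the unit; offsets where at least
    ``min_fraction`` of window positions match some rotation seed a tract,
    and seeds separated by less than ``merge_gap`` (default two units) are
    merged.  Returns maximal merged intervals, longest first.
    """
    if not read:
        raise ValueError("empty read")
    e = spec.unit_length
    window = 2 * e
    if len(read) < window:
        return []
    if merge_gap is None:
        merge_gap = 2 * e
    arr = np.frombuffer(read.upper().encode(), dtype=np.uint8)
    codes = np.full(arr.shape, 255, dtype=np.uint8)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    n_win = len(read) - window + 1
    best = np.zeros(n_win, dtype=np.int32)
    rotations = canonical_rotations(spec.pattern)
    for offset in range(e):
        if rotations and offset >= len(rotations) and spec.mixed_weights is None:
            break  # periodic unit: remaining offsets duplicate earlier ones
        table = _accept_table(spec, spec.pattern, offset)
        acc = np.zeros(n_win, dtype=np.int32)
        for w in range(window):
            col = codes[w : w + n_win]
            hit = np.zeros(n_win, dtype=bool)
            for b in range(4):
                if table[w, b]:
                    hit |= col == b
            acc += hit
        np.maximum(best, acc, out=best)
    need = math.ceil(min_fraction * window)
    seeds = np.nonzero(best >= need)[0]
    if len(seeds) == 0:
        return []

    upper = read.upper()

    def refine(start: int, end: int) -> TractCandidate:
        # Trim edge bases whose full unit breaks periodicity, so clean
        # tracts are recovered exactly even when a flank base happens to
        # complete an almost-matching window.  Trims are capped at one unit
        # per side: deeper aperiodicity is sequencing error inside the
        # tract, not boundary slop, and must stay in the tract.
        lo_cap = start + e
        while (
            start < lo_cap
            and end - start > 2 * e
            and upper[start : start + e] != upper[start + e : start + 2 * e]
        ):
            start += 1
        hi_cap = end - e
        while (
            end > hi_cap
            and end - start > 2 * e
            and upper[end - e : end] != upper[end - 2 * e : end - e]
        ):
            end -= 1
        # A flank base can genuinely extend the periodicity by a partial
        # unit (e.g. a tract ending CAG followed by C, or preceded by G);
        # canonicalise to whole units, preferring the trim that leaves the
        # tract starting on the repeat unit itself.
        r = (end - start) % e
        if 0 < r < end - start - 2 * e:
            pattern = spec.pattern.upper()
            if (
                upper[start : start + e] != pattern
                and upper[start + r : start + r + e] == pattern
            ):
                start += r
            elif upper[end - r : end] == upper[end - r - e : end - e]:
                end -= r
        return TractCandidate(start, end, (end - start) / e)

    tracts: list[TractCandidate] = []
    run_start = prev = int(seeds[0])
    for s in seeds[1:]:
        s = int(s)
        # Each seed covers [seed, seed + window); merge unless the covered
        # intervals are separated by at least merge_gap bases.
        if s - (prev + window) >= merge_gap:
            tracts.append(refine(run_start, prev + window))
            run_start = s
        prev = s
    tracts.append(refine(run_start, prev + window))
    return sorted(tracts, key=lambda t: (-t.length, t.start))


def chain_candidates(
    tracts: list[TractCandidate], unit_length: int, chain_gap: int | None = None
) -> TractCandidate:
    """Join split pieces of one noisy tract into a single interval.

    Error clusters can break a long tract into several candidates; pieces
    of at least four units lying within ``chain_gap`` (default ten units)
    of the longest piece are merged with it.  Shorter candidates — mostly
    chance repeat-like windows in flanking sequence, which would inflate
    the count if absorbed — never join a chain.
    """
    if not tracts:
        raise ValueError("no candidates to chain")
    if chain_gap is None:
        chain_gap = 10 * unit_length
    big = [t for t in tracts if t.length >= 4 * unit_length]
    if not big:
        return tracts[0]
    seed = max(big, key=lambda t: t.length)
    start, end = seed.start, seed.end
    changed = True
    while changed:
        changed = False
        for t in big:
            if t.start <= end + chain_gap and t.end >= start - chain_gap and (
                t.start < start or t.end > end
            ):
                start = min(start, t.start)
                end = max(end, t.end)
                changed = True
    return TractCandidate(start, end, (end - start) / unit_length)


def _infix_align(query: str, window: str) -> tuple[int, int, float]:
    """Best infix placement of ``query`` in ``window``: (start, end, identity)."""
    res = edlib.align(query, window, mode="HW", task="locations")
    dist = res["editDistance"]
    start, end = res["locations"][0]
    return int(start), int(end) + 1, 1.0 - dist / max(1, len(query))


def align_flanks(upstream: str, downstream: str, reference_window: str) -> FlankAnchors:
    """Anchor both flanks in the reference window by infix alignment."""
    if len(reference_window) < max(len(upstream), len(downstream)):
        raise ValueError("reference window shorter than a flank")
    us, ue, ui = _infix_align(upstream, reference_window)
    ds, de, di = _infix_align(downstream, reference_window)
    return FlankAnchors(us, ue, ui, ds, de, di, )


def _fallback_tract(
    seq: str, locus: LocusReference
) -> tuple[int, int] | None:
    """Whole-read infix alignment; maps the reference tract into read coords."""
    res = edlib.align(seq, locus.sequence, mode="HW", task="path")
    if res["editDistance"] < 0:
        return None
    identity = 1.0 - res["editDistance"] / max(1, len(seq))
    if identity < 0.5:  # hopeless alignment; treat as unaligned
        return None
    ref_pos = res["locations"][0][0]
    read_pos = 0
    t_start_ref = locus.spec.start - 1
    t_end_ref = locus.spec.end
    t_start = t_end = None
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        ln = int(num)
        num = ""
        consumes_read = ch in "=XIM"
        consumes_ref = ch in "=XDM"
        for _ in range(ln):
            if t_start is None and ref_pos >= t_start_ref:
                t_start = read_pos
            if t_end is None and ref_pos >= t_end_ref:
                t_end = read_pos
            read_pos += 1 if consumes_read else 0
            ref_pos += 1 if consumes_ref else 0
        if t_start is not None and t_end is not None:
            break
    if t_end is None and ref_pos >= t_end_ref:
        t_end = read_pos
    if t_start is None or t_end is None or t_end <= t_start:
        return None
    return t_start, t_end


def localize_read(
    read_id: str,
    sequence: str,
    locus: LocusReference,
    identity_threshold: float = 0.8,
    min_fraction: float = 0.8,
) -> LocalizedRead | RejectedRead:
    """Split-and-align localization with whole-read fallback.

    Tries the forward orientation first, then the reverse complement; the
    reverse-strand read is reverse-complemented so every accepted read is
    forward-oriented.  Rejections carry a reason code: ``no_tract`` (no
    repeat-like window on either strand), ``short_flank`` (a flank below
    ``spec.min_flank``), ``low_identity`` (flanks anchor poorly or out of
    order), ``unaligned`` (fallback alignment also failed).
    """
    spec = locus.spec
    saw_tract = False
    flank_failure: str | None = None
    for oriented in (sequence.upper(), reverse_complement(sequence.upper())):
        strand = "+" if oriented == sequence.upper() else "-"
        tracts = find_tandem_tracts(oriented, spec, min_fraction=min_fraction)
        if not tracts:
            continue
        saw_tract = True
        tract = chain_candidates(tracts, spec.unit_length)
        upstream = oriented[: tract.start]
        downstream = oriented[tract.end :]
        if len(upstream) < spec.min_flank or len(downstream) < spec.min_flank:
            flank_failure = flank_failure or "short_flank"
            continue
        anchors = align_flanks(upstream, downstream, locus.sequence)
        if anchors.min_identity < identity_threshold or not anchors.ordered:
            flank_failure = flank_failure or "low_identity"
            continue
        return LocalizedRead(
            read_id=read_id,
            sequence=oriented,
            tract_start=tract.start,
            tract_end=tract.end,
            anchored=True,
            strand=strand,
            pad=TRACT_PAD_UNITS * spec.unit_length,
        )
    # Fallback: whole-read alignment against the locus window.
    best: LocalizedRead | None = None
    best_identity = -1.0
    for oriented in (sequence.upper(), reverse_complement(sequence.upper())):
        strand = "+" if oriented == sequence.upper() else "-"
        res = edlib.align(oriented, locus.sequence, mode="HW")
        identity = 1.0 - res["editDistance"] / max(1, len(oriented))
        if identity < identity_threshold or identity <= best_identity:
            continue
        bounds = _fallback_tract(oriented, locus)
        if bounds is None:
            continue
        t_start, t_end = bounds
        if t_start < spec.min_flank or len(oriented) - t_end < spec.min_flank:
            flank_failure = flank_failure or "short_flank"
            continue
        best = LocalizedRead(
            read_id=read_id,
            sequence=oriented,
            tract_start=t_start,
            tract_end=t_end,
            anchored=False,
            strand=strand,
        )
        best_identity = identity
    if best is not None:
        return best
    if flank_failure is not None:
        return RejectedRead(read_id, flank_failure)
    if not saw_tract:
        return RejectedRead(read_id, "no_tract")
    return RejectedRead(read_id, "unaligned")
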