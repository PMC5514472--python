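"""Error correction of repeat regions by asymmetric-gap alignment.

A detected repeat region is globally aligned against a perfect-repeat
template 50% longer than the region.  The two sequences have very different
error rates — the template has none — so the aligner charges far more for a
gap in the read (a skipped template base, i.e. a read deletion) than for a
gap in the template (an extra read base, i.e. a read insertion).  Bases of
the read that align opposite template gaps are physically removed from the
corrected output; template bases opposite read gaps are *not* re-inserted,
because the downstream HMM's deletion states account for them.

The alignment is banded for speed; the band is centred on the
corner-to-corner diagonal so a template longer than the query remains
reachable end-to-end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from ._kernels import DIAG, GAP_READ, GAP_TMPL, NEG_INF, banded_global_align

__all__ = [
    "AlignParams",
    "Alignment",
    "BandTooNarrowError",
    "make_perfect_template",
    "unsym_align",
    "correct_read_region",
]


class BandTooNarrowError(RuntimeError):
    """The band cannot connect the alignment corners; increase band_width."""


@dataclass(frozen=True)
class AlignParams:
    """Scoring for the asymmetric-gap aligner.

    ``gap_in_read`` (default −10) is the penalty for leaving a template base
    unmatched inside the alignment; ``gap_in_perf`` (default −1) for leaving
    a read base unmatched.  With ``fit_template`` (the default) the
    template's overhanging ends are free, since the perfect-repeat template
    is deliberately built 50% longer than the region it corrects; without
    it the alignment is fully global on both sequences.  ``band_width`` of
    None selects ``max(32, ceil(0.3 * len(template)))``.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_in_perf: float = -1.0
    gap_in_read: float = -10.0
    band_width: int | None = None
    fit_template: bool = True

    def __post_init__(self) -> None:
        if not self.gap_in_read <= self.gap_in_perf <= 0.0 <= self.match:
            raise ValueError("require gap_in_read <= gap_in_perf <= 0 <= match")
        if self.band_width is not None and self.band_width < 1:
            raise ValueError("band_width must be >= 1")

    def effective_band(self, template_len: int) -> int:
        if self.band_width is not None:
            return self.band_width
        return max(32, math.ceil(0.3 * template_len))


@dataclass(frozen=True)
class Alignment:
    """Gapped alignment plus the corrected (insertion-stripped) query."""

    aligned_query: str
    aligned_template: str
    score: float
    corrected: str

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_template):
            raise ValueError("gapped strings must have equal length")


def make_perfect_template(pattern: str, region_len: int) -> str:
    """Perfect-repeat template covering 1.5x the region, whole units only.

    Total length is ceil(1.5 * region_len) rounded up to a multiple of the
    unit length, guaranteeing slack for reads inflated by insertions.
    """
    if not pattern:
        raise ValueError("empty pattern")
    if region_len < 1:
        raise ValueError("region_len must be >= 1")
    target = math.ceil(1.5 * region_len)
    units = math.ceil(target / len(pattern))
    return pattern * units


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


def unsym_align(query: str, template: str, params: AlignParams | None = None) -> Alignment:
    """Optimal banded global alignment of a read region to a repeat template.

    Traceback ties prefer diagonal moves, then template gaps, then read
    gaps, making the result deterministic.  ``corrected`` is the query with
    every base aligned opposite a template gap removed.

    Raises :class:`BandTooNarrowError` when the band cannot connect the
    corners.
    """
    if not query or not template:
        raise ValueError("query and template must be non-empty")
    params = params or AlignParams()
    band = params.effective_band(len(template))
    score, start_j, end_j, moves = banded_global_align(
        _encode(query),
        _encode(template),
        float(params.match),
        float(params.mismatch),
        float(params.gap_in_perf),
        float(params.gap_in_read),
        band,
        1 if params.fit_template else 0,
    )
    if score <= NEG_INF / 2:
        raise BandTooNarrowError(
            f"band_width={band} cannot connect the corners for lengths "
            f"{len(query)}x{len(template)}; increase band_width"
        )
    aq: list[str] = []
    at: list[str] = []
    corrected: list[str] = []
    qi = 0
    ti = start_j
    # Free template overhangs are shown as read gaps so ungapping the
    # alignment strings recovers both full inputs; they carry no score.
    for k in range(start_j):
        aq.append("-")
        at.append(template[k])
    for mv in moves:
        if mv == DIAG:
            aq.append(query[qi])
            at.append(template[ti])
            corrected.append(query[qi])
            qi += 1
            ti += 1
        elif mv == GAP_TMPL:  # read insertion: dropped from corrected
            aq.append(query[qi])
            at.append("-")
            qi += 1
        elif mv == GAP_READ:  # read deletion: left absent from corrected
            aq.append("-")
            at.append(template[ti])
            ti += 1
    for k in range(end_j, len(template)):
        aq.append("-")
        at.append(template[k])
    return Alignment(
        aligned_query="".join(aq),
        aligned_template="".join(at),
        score=float(score),
        corrected="".join(corrected),
    )


def correct_read_region(
    region: str, pattern: str, params: AlignParams | None = None
) -> str:
    """Correct a repeat region against its perfect-repeat template.

    Composition of :func:`make_perfect_template` and :func:`unsym_align`;
    if the configured band cannot connect the corners the band is doubled
    (bounded) before giving up.
    """
    if not region:
        raise ValueError("empty region")
    if not pattern:
        raise ValueError("empty pattern")
    params = params or AlignParams()
    template = make_perfect_template(pattern, len(region))
    band = params.effective_band(len(template))
    limit = 2 * max(len(region), len(template))
    while True:
        try:
            trial = replace(params, band_width=band)
            return unsym_align(region, template, trial).corrected
        except BandTooNarrowError:
            if band >= limit:
                raise
            band = min(2 * band, limit)
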