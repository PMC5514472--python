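"""Analytic repeat HMM: model construction, Viterbi decoding, repeat counting.

The model for a unit of length E has N = 3E + 1 hidden states: one NonRepeat
state plus, for each unit position k, a match state ``r_k``, an
insertion-after state ``Ir_k`` and a deletion-of state ``Dr_k``.  Observed
symbols are A, C, G, T, N.  All matrices are built analytically from the
repeat unit and an :class:`~tandemhmm.repeat_spec.ErrorProfile` — nothing is
trained from data.

Matrix construction rules
-------------------------
Emission (substitution / random-emission rate ``s``):

* match ``r_k`` emits unit position k with ``1 - 3s/4`` and each other
  nucleotide with ``s/4`` (a mixed position with weights ``w_b`` emits base
  b with ``(1 - s) * w_b + s/4``, which reduces to the former for a point
  mass);
* deletion ``Dr_k`` represents a skipped unit base and emits the *next*
  unit position (k+1, wrapping) with the same match-style distribution;
* insertion states emit 0.25 over A/C/G/T;
* NonRepeat emits 0.2 over all five symbols.  Match/insertion/deletion
  states never emit N, which is what lets inserted N separators force the
  NonRepeat state.

Transition (insertion rate ``i``, deletion rate ``d``, region entry/exit
``region_io``, NonRepeat self-transition ``n``): insertions
``r_k/Ir_k/Dr_(k-1) -> Ir_k`` get ``i``; deletions ``NonRepeat -> Dr_1`` and
``r_(k-1)/Ir_(k-1)/Dr_(k-2) -> Dr_k`` get ``d``; ``NonRepeat -> r_1`` and
each of ``r_E/Ir_E/Dr_(E-1)/Dr_E -> NonRepeat`` get ``region_io``;
``NonRepeat -> NonRepeat`` gets ``n``; every other transition gets a small
epsilon; and each row's expected transition (``-> r_k`` for repeat states,
the self-loop for NonRepeat) absorbs the remainder so rows sum to one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._kernels import NEG_INF, viterbi_kernel
from .repeat_spec import ErrorProfile, RepeatSpec

__all__ = [
    "SYMBOLS",
    "HmmModel",
    "StatePath",
    "build_states",
    "build_emission_matrix",
    "build_transition_matrix",
    "build_start_probs",
    "build_model",
    "viterbi",
    "repeat_count_from_path",
]

SYMBOLS = ("A", "C", "G", "T", "N")
_SYM_INDEX = {s: i for i, s in enumerate(SYMBOLS)}

#: Probability "close to 0" assigned to non-expected transitions; strictly
#: positive so corrupt reads stay decodable, numerically negligible.
EPSILON = 1e-9


def build_states(unit_length: int) -> list[str]:
    """Ordered state labels: NonRepeat, r1..rE, Ir1..IrE, Dr1..DrE."""
    if unit_length < 1:
        raise ValueError("unit length must be >= 1")
    e = unit_length
    return (
        ["NonRepeat"]
        + [f"r{k}" for k in range(1, e + 1)]
        + [f"Ir{k}" for k in range(1, e + 1)]
        + [f"Dr{k}" for k in range(1, e + 1)]
    )


def _match_index(e: int, k: int) -> int:
    """State index of r_k with 1-based k wrapping modulo E."""
    return 1 + (k - 1) % e


def _ins_index(e: int, k: int) -> int:
    return 1 + e + (k - 1) % e


def _del_index(e: int, k: int) -> int:
    return 1 + 2 * e + (k - 1) % e


def _emission_row(spec: RepeatSpec, pos: int, sub_rate: float) -> np.ndarray:
    """Match-style emission distribution for 1-based unit position ``pos``."""
    row = np.full(5, sub_rate / 4.0)
    row[4] = 0.0  # repeat states never emit N
    for base, w in spec.unit_distribution(1 + (pos - 1) % spec.unit_length).items():
        row[_SYM_INDEX[base]] = (1.0 - sub_rate) * w + sub_rate / 4.0
    return row


def build_emission_matrix(spec: RepeatSpec, sub_rate: float) -> np.ndarray:
    """Row-stochastic (3E+1, 5) emission matrix for the locus."""
    if not 0.0 <= sub_rate < 1.0:
        raise ValueError("sub_rate must be in [0, 1)")
    e = spec.unit_length
    emit = np.zeros((3 * e + 1, 5))
    emit[0, :] = 0.2
    for k in range(1, e + 1):
        emit[_match_index(e, k)] = _emission_row(spec, k, sub_rate)
        # Dr_k emits the base following the deleted one (DrE wraps to pos 1).
        emit[_del_index(e, k)] = _emission_row(spec, k + 1, sub_rate)
        emit[_ins_index(e, k), :4] = 0.25
    return emit


def build_transition_matrix(unit_length: int, profile: ErrorProfile) -> np.ndarray:
    """Row-stochastic (3E+1, 3E+1) transition matrix from the error profile."""
    e = unit_length
    n_states = 3 * e + 1
    i, d = profile.ins_rate, profile.del_rate
    io, n_self = profile.region_io, profile.nonrepeat_self
    trans = np.full((n_states, n_states), EPSILON)

    def fill_row(row: int, fixed: dict[int, float], absorber: int) -> None:
        for col, p in fixed.items():
            trans[row, col] = p
        others = trans[row].sum() - trans[row, absorber]
        remainder = 1.0 - others
        if remainder <= 0.0:
            raise ValueError("error profile infeasible: expected transition <= 0")
        trans[row, absorber] = remainder

    # NonRepeat row: enter repeat (r1) or delete-enter (Dr1); the self-loop
    # carries nonrepeat_self and the row is normalised (for the default
    # profile n + io + d = 1 already, so this only absorbs epsilon mass).
    trans[0, _match_index(e, 1)] = io
    trans[0, _del_index(e, 1)] = d
    trans[0, 0] = n_self
    if trans[0, 0] <= 0:
        raise ValueError("nonrepeat_self must be positive")
    trans[0] /= trans[0].sum()
    exits = {_match_index(e, e), _ins_index(e, e), _del_index(e, e - 1) if e > 1 else _del_index(e, e), _del_index(e, e)}
    for k in range(1, e + 1):
        for row in (_match_index(e, k), _ins_index(e, k)):
            fixed = {_ins_index(e, k): i, _del_index(e, k + 1): d}
            if row in exits:
                fixed[0] = io
            fill_row(row, fixed, absorber=_match_index(e, k + 1))
        row = _del_index(e, k)
        fixed = {_ins_index(e, k + 1): i, _del_index(e, k + 2): d}
        if row in exits:
            fixed[0] = io
        fill_row(row, fixed, absorber=_match_index(e, k + 2))
    return trans


def build_start_probs(unit_length: int, profile: ErrorProfile) -> np.ndarray:
    """Start vector mirroring the NonRepeat transition row.

    A decoded segment starts in flanking sequence, so the mass sits on
    NonRepeat with ``region_io`` for starting directly in r1 and
    ``del_rate`` for Dr1 (matching how the NonRepeat state hands off).
    """
    e = unit_length
    start = np.full(3 * e + 1, EPSILON)
    start[_match_index(e, 1)] = profile.region_io
    start[_del_index(e, 1)] = profile.del_rate
    start[0] = 1.0 - (start.sum() - start[0])
    if start[0] <= 0:
        raise ValueError("error profile infeasible for start probabilities")
    return start


@dataclass(frozen=True)
class HmmModel:
    """A fully built repeat HMM for one locus and error profile."""

    states: tuple[str, ...]
    emission: np.ndarray
    transition: np.ndarray
    start: np.ndarray
    unit_length: int
    profile: ErrorProfile

    def __post_init__(self) -> None:
        n = 3 * self.unit_length + 1
        if len(self.states) != n:
            raise ValueError("state count must be 3E + 1")
        for name, mat in (("emission", self.emission), ("transition", self.transition)):
            if (mat < 0).any():
                raise ValueError(f"{name} matrix has negative entries")
            if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must sum to 1")
        if abs(self.start.sum() - 1.0) > 1e-9:
            raise ValueError("start vector must sum to 1")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def log_matrices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        with np.errstate(divide="ignore"):
            ls = np.where(self.start > 0, np.log(self.start), NEG_INF)
            lt = np.where(self.transition > 0, np.log(self.transition), NEG_INF)
            le = np.where(self.emission > 0, np.log(self.emission), NEG_INF)
        return ls, lt, le

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "states": list(self.states),
            "symbols": list(SYMBOLS),
            "emission": self.emission.tolist(),
            "transition": self.transition.tolist(),
            "start": self.start.tolist(),
            "unit_length": self.unit_length,
            "profile": vars(self.profile),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "HmmModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(
            states=tuple(payload["states"]),
            emission=np.asarray(payload["emission"], dtype=float),
            transition=np.asarray(payload["transition"], dtype=float),
            start=np.asarray(payload["start"], dtype=float),
            unit_length=int(payload["unit_length"]),
            profile=ErrorProfile(**payload["profile"]),
        )


def build_model(spec: RepeatSpec, profile: ErrorProfile | None = None) -> HmmModel:
    """Build the complete HMM for ``spec`` under ``profile`` (PacBio default)."""
    profile = profile or ErrorProfile()
    e = spec.unit_length
    return HmmModel(
        states=tuple(build_states(e)),
        emission=build_emission_matrix(spec, profile.sub_rate),
        transition=build_transition_matrix(e, profile),
        start=build_start_probs(e, profile),
        unit_length=e,
        profile=profile,
    )


@dataclass(frozen=True)
class StatePath:
    """Viterbi decoding result: one state index per observed symbol."""

    states: np.ndarray
    log_likelihood: float

    def __len__(self) -> int:
        return len(self.states)


def encode_observations(obs: str) -> np.ndarray:
    arr = np.frombuffer(obs.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for sym, idx in _SYM_INDEX.items():
        out[arr == ord(sym)] = idx
    if (out < 0).any():
        bad = sorted(set(obs[i] for i in np.nonzero(out < 0)[0]))
        raise ValueError(f"observation contains non-{'/'.join(SYMBOLS)} symbol(s) {bad}")
    return out


def viterbi(obs: str, model: HmmModel) -> StatePath:
    """Maximum-probability state path for ``obs``, decoded in log space.

    Ties are broken toward the lower state index during backtrace, making
    the path deterministic.
    """
    if not obs:
        raise ValueError("empty observation")
    codes = encode_observations(obs)
    ls, lt, le = model.log_matrices()
    # An observation column that no state can emit would make every path
    # impossible; the model never produces one (NonRepeat emits everything).
    if np.any(le[:, codes].max(axis=0) <= NEG_INF / 2):
        raise ValueError("observation impossible under the model")
    path, loglik = viterbi_kernel(ls, lt, le, codes)
    return StatePath(states=path.astype(np.int64), log_likelihood=float(loglik))


def repeat_count_from_path(path: StatePath, unit_length: int) -> int:
    """Repeat count from a decoded path.

    Each match-state position contributes one tract base and each
    deletion-state position two (the emitted base plus the skipped one);
    insertion-state positions contribute nothing.  The reconstructed tract
    length is divided by the unit length and rounded half-up.
    """
    e = unit_length
    s = np.asarray(path.states)
    n_match = int(((s >= 1) & (s <= e)).sum())
    n_del = int((s >= 2 * e + 1).sum())
    length = n_match + 2 * n_del
    return int(np.floor(length / e + 0.5))
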