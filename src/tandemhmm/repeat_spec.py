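"""Repeat-locus definitions and sequencing error profiles.

A :class:`RepeatSpec` names a microsatellite locus (gene, chromosome,
1-based inclusive start/end as in genome-browser convention) and its repeat
unit, optionally with position-wise mixed patterns (e.g. an ATTCT tract in
which position 3 is C in 40% of units and T in 60%).  An
:class:`ErrorProfile` carries the per-base insertion / deletion /
substitution rates of the sequencing platform together with the structural
rates of the repeat HMM (non-repeat self-transition and region entry/exit).

All other modules consume these two types.  Coordinates are converted to
0-based half-open exactly once, at config load.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

__all__ = [
    "MAX_UNIT_LENGTH",
    "RepeatSpec",
    "ErrorProfile",
    "LocusReference",
    "load_repeat_specs",
    "canonical_rotations",
    "reverse_complement",
]

#: Engineering cap on repeat-unit length (the model itself has no such limit).
MAX_UNIT_LENGTH = 60

_NUCS = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class SpecError(ValueError):
    """Raised for malformed locus configurations."""


@dataclass(frozen=True)
class RepeatSpec:
    """Definition of one microsatellite repeat locus.

    ``start``/``end`` are 1-based inclusive genomic coordinates of the repeat
    tract in the reference.  ``pattern`` is the repeat unit on the forward
    strand.  ``mixed_weights`` maps a 1-based position within the unit to a
    nucleotide->probability distribution for position-independent mixed
    patterns; positions not listed emit the unit nucleotide deterministically.
    """

    gene_name: str
    chrom: str
    start: int
    end: int
    pattern: str
    mixed_weights: Mapping[int, Mapping[str, float]] | None = None
    min_flank: int = 18

    def __post_init__(self) -> None:
        if not self.pattern:
            raise SpecError(f"{self.gene_name}: empty repeat unit")
        if not 1 <= len(self.pattern) <= MAX_UNIT_LENGTH:
            raise SpecError(
                f"{self.gene_name}: unit length {len(self.pattern)} outside "
                f"[1, {MAX_UNIT_LENGTH}]"
            )
        bad = set(self.pattern) - _NUCS
        if bad:
            raise SpecError(f"{self.gene_name}: invalid nucleotide(s) {sorted(bad)}")
        if self.start > self.end:
            raise SpecError(f"{self.gene_name}: start {self.start} > end {self.end}")
        if self.min_flank < 1:
            raise SpecError(f"{self.gene_name}: min_flank must be >= 1")
        if self.mixed_weights is not None:
            norm: dict[int, dict[str, float]] = {}
            for pos, dist in self.mixed_weights.items():
                pos = int(pos)
                if not 1 <= pos <= len(self.pattern):
                    raise SpecError(
                        f"{self.gene_name}: mixed position {pos} outside unit"
                    )
                bad = set(dist) - _NUCS
                if bad:
                    raise SpecError(
                        f"{self.gene_name}: invalid mixed base(s) {sorted(bad)}"
                    )
                total = float(sum(dist.values()))
                if total <= 0:
                    raise SpecError(f"{self.gene_name}: mixed weights sum to 0")
                norm[pos] = {b: float(w) / total for b, w in dist.items()}
                if abs(sum(norm[pos].values()) - 1.0) > 1e-9:
                    raise SpecError(f"{self.gene_name}: mixed weights not normalisable")
            object.__setattr__(self, "mixed_weights", norm)

    @property
    def unit_length(self) -> int:
        return len(self.pattern)

    @property
    def tract_slice(self) -> slice:
        """0-based half-open slice of the tract in the reference."""
        return slice(self.start - 1, self.end)

    def unit_distribution(self, pos: int) -> dict[str, float]:
        """Emission target distribution for 1-based unit position ``pos``.

        A point mass on the unit nucleotide unless the position is mixed.
        """
        if self.mixed_weights and pos in self.mixed_weights:
            return dict(self.mixed_weights[pos])
        return {self.pattern[pos - 1]: 1.0}


@dataclass(frozen=True)
class ErrorProfile:
    """Per-base error rates plus the HMM's structural transition rates.

    Defaults follow the PacBio continuous-long-read profile: 11% insertions,
    2% deletions, 2% substitutions, with 0.96 non-repeat self-transition and
    0.02 probability of entering/leaving the repeat region.
    """

    ins_rate: float = 0.11
    del_rate: float = 0.02
    sub_rate: float = 0.02
    nonrepeat_self: float = 0.96
    region_io: float = 0.02

    def __post_init__(self) -> None:
        for name in ("ins_rate", "del_rate", "sub_rate", "nonrepeat_self", "region_io"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SpecError(f"{name}={v} outside [0, 1]")
        # Expected-transition rows must retain positive remainder mass.
        if self.ins_rate + self.del_rate + self.region_io >= 1.0:
            raise SpecError("ins_rate + del_rate + region_io must be < 1")

    def with_rates(self, **kw: float) -> "ErrorProfile":
        return replace(self, **kw)


@dataclass(frozen=True)
class LocusReference:
    """A repeat spec together with the reference sequence it indexes into.

    ``spec.start``/``spec.end`` are 1-based inclusive coordinates *within*
    ``sequence`` (a locus-scale reference window, not a whole genome).
    """

    spec: RepeatSpec
    sequence: str

    def __post_init__(self) -> None:
        if self.spec.end > len(self.sequence):
            raise SpecError("spec coordinates exceed reference sequence")
        tract = self.tract_sequence
        unit = self.spec.pattern
        if tract[: len(unit)] != unit:
            raise SpecError("reference tract does not start with the repeat unit")

    @property
    def tract_sequence(self) -> str:
        return self.sequence[self.spec.tract_slice]

    @property
    def upstream(self) -> str:
        return self.sequence[: self.spec.start - 1]

    @property
    def downstream(self) -> str:
        return self.sequence[self.spec.end :]

    @property
    def reference_units(self) -> int:
        return len(self.tract_sequence) // self.spec.unit_length


def canonical_rotations(pattern: str) -> list[str]:
    """All distinct cyclic rotations of ``pattern``, original first.

    Supports tract detection when a read enters the repeat mid-unit.  The
    number of distinct rotations divides the unit length and equals it iff
    the unit is aperiodic.
    """
    if not pattern:
        raise SpecError("empty pattern has no rotations")
    seen: dict[str, None] = {}
    doubled = pattern + pattern
    for i in range(len(pattern)):
        seen.setdefault(doubled[i : i + len(pattern)])
    return list(seen)


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N} (case-preserving); N maps to N."""
    bad = set(seq.upper()) - (_NUCS | {"N"})
    if bad:
        raise SpecError(f"cannot reverse-complement symbol(s) {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def _parse_mixed_tokens(tokens: str) -> dict[int, dict[str, float]]:
    """Parse ``"pos:base=weight,pos:base=weight"`` tokens from TSV configs."""
    weights: dict[int, dict[str, float]] = {}
    for tok in tokens.replace(";", ",").split(","):
        tok = tok.strip()
        if not tok:
            continue
        try:
            pos_s, assign = tok.split(":", 1)
            base, w = assign.split("=", 1)
            weights.setdefault(int(pos_s), {})[base.strip().upper()] = float(w)
        except ValueError as exc:
            raise SpecError(f"malformed mixed-weight token {tok!r}") from exc
    return weights


def _record_to_spec(rec: Mapping[str, object], where: str) -> RepeatSpec:
    try:
        mixed = rec.get("mixed_weights") or None
        if isinstance(mixed, str):
            mixed = _parse_mixed_tokens(mixed) or None
        elif isinstance(mixed, Mapping):
            mixed = {int(k): dict(v) for k, v in mixed.items()}
        return RepeatSpec(
            gene_name=str(rec["gene"]),
            chrom=str(rec["chrom"]),
            start=int(rec["start"]),
            end=int(rec["end"]),
            pattern=str(rec["pattern"]).upper(),
            mixed_weights=mixed,
            min_flank=int(rec.get("min_flank", 18) or 18),
        )
    except KeyError as exc:
        raise SpecError(f"{where}: missing field {exc.args[0]!r}") from exc
    except (TypeError, ValueError) as exc:
        raise SpecError(f"{where}: {exc}") from exc


def load_repeat_specs(config_path: str | Path) -> list[RepeatSpec]:
    """Load locus definitions from a JSON or TSV config file.

    JSON: a list of objects with fields ``gene, chrom, start, end, pattern``
    and optional ``mixed_weights`` (position -> base -> weight) and
    ``min_flank``.  TSV: one locus per line with the same columns in that
    order; mixed weights as ``pos:base=weight`` tokens.  Parse errors carry
    the offending record/line.
    """
    path = Path(config_path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    specs: list[RepeatSpec] = []
    if path.suffix.lower() == ".json" or text.lstrip().startswith(("[", "{")):
        records = json.loads(text)
        if isinstance(records, Mapping):
            records = [records]
        for i, rec in enumerate(records):
            specs.append(_record_to_spec(rec, f"{path.name} record {i}"))
        return specs
    columns = ["gene", "chrom", "start", "end", "pattern", "mixed_weights", "min_flank"]
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("gene\t"):
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise SpecError(f"{path.name} line {lineno}: expected >= 5 columns")
        rec = dict(zip(columns, fields))
        specs.append(_record_to_spec(rec, f"{path.name} line {lineno}"))
    return specs
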