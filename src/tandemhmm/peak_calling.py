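"""Allele calling from per-read repeat counts.

The per-read counts from a sample form a histogram that is modelled as a
mixture of Gaussians: one dominant component per allele plus minor
components absorbing noise.  The procedure is:

1. filter the raw counts (drop counts below a minimum, default 5, and
   histogram bins with too few supporting reads, default 3);
2. fit 1-D Gaussian mixtures with k components for k in 3..7 (default),
   20 restarts each, and select the fit minimising AIC subject to the rule
   that the chosen k must not be an endpoint of the tried range;
3. filter components so that a component with a smaller mean also has a
   smaller standard deviation and more supporting reads than any retained
   component to its left;
4. take the component with the most supporting reads as the first allele;
   accept a second peak if its mean is larger, or — when smaller — if its
   support exceeds 80% (default) of the first peak's support.

One surviving peak means a homozygous call.  Peak repeat counts are the
rounded component means.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "CountHistogram",
    "GmmFit",
    "AlleleCall",
    "filter_counts",
    "fit_gmm",
    "select_model",
    "call_alleles",
    "call_from_counts",
]

logger = logging.getLogger(__name__)

#: Variance regularisation keeping components from collapsing on integer
#: data; acts as a standard-deviation floor of about 0.25.
SD_FLOOR = 0.25


class NoInformativeReadsError(ValueError):
    """Every per-read count was filtered out."""


@dataclass(frozen=True)
class CountHistogram:
    """Filtered per-read repeat-count histogram."""

    counts: dict[int, int]
    total_reads: int

    def expand(self) -> np.ndarray:
        out: list[int] = []
        for value in sorted(self.counts):
            out.extend([value] * self.counts[value])
        return np.asarray(out, dtype=float)

    @property
    def distinct(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class GmmFit:
    """Best-of-restarts Gaussian mixture fit for one component count."""

    n_components: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    aic: float
    support: np.ndarray  # reads hard-assigned to each component

    def __post_init__(self) -> None:
        if abs(self.weights.sum() - 1.0) > 1e-6:
            raise ValueError("weights must sum to 1")
        if (self.sds <= 0).any():
            raise ValueError("sds must be positive")


@dataclass(frozen=True)
class AlleleCall:
    """One or two allele repeat counts with supporting-read tallies."""

    allele1: int
    allele2: int
    support1: int
    support2: int
    zygosity: str

    def __post_init__(self) -> None:
        if self.allele1 > self.allele2:
            raise ValueError("allele1 must be <= allele2")
        if self.allele1 < 1:
            raise ValueError("allele counts must be >= 1")

    @property
    def alleles(self) -> tuple[int, int]:
        return (self.allele1, self.allele2)


def filter_counts(
    raw: list[int], min_count: int = 5, min_reads: int = 3
) -> CountHistogram:
    """Histogram of per-read counts after the two filtering rules.

    Counts below ``min_count`` are dropped, then histogram bins supported by
    fewer than ``min_reads`` reads are dropped.  Raises
    :class:`NoInformativeReadsError` when nothing survives.
    """
    if not raw:
        raise NoInformativeReadsError("no per-read counts supplied")
    tally = Counter(int(c) for c in raw if c >= min_count)
    kept = {v: n for v, n in sorted(tally.items()) if n >= min_reads}
    if not kept:
        raise NoInformativeReadsError(
            f"no informative reads: {len(raw)} counts all below min_count="
            f"{min_count} or in bins below min_reads={min_reads}"
        )
    return CountHistogram(counts=kept, total_reads=sum(kept.values()))


def _kmeanspp_init(
    values: np.ndarray, weights: np.ndarray, k: int, n_restarts: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_restarts, k) initial means by weighted k-means++ sampling."""
    means = np.empty((n_restarts, k))
    probs = weights / weights.sum()
    for r in range(n_restarts):
        centres = [values[rng.choice(len(values), p=probs)]]
        while len(centres) < k:
            d2 = np.min((values[:, None] - np.array(centres)[None, :]) ** 2, axis=1)
            p = weights * d2
            if p.sum() <= 0:  # all remaining mass on chosen centres
                p = np.where(np.isin(values, centres), 0.0, weights)
                if p.sum() <= 0:
                    p = weights.astype(float)
            centres.append(values[rng.choice(len(values), p=p / p.sum())])
        means[r] = centres
    return means


def fit_gmm(
    hist: CountHistogram,
    n_components: int,
    n_restarts: int = 20,
    seed: int | np.random.Generator | None = 0,
) -> GmmFit:
    """Best of ``n_restarts`` EM fits with ``n_components`` components.

    A dedicated weighted 1-D EM over the histogram (mathematically
    identical to EM on the expanded per-read count list, but linear in the
    number of *distinct* counts), with all restarts advanced together as a
    numpy batch.  Restarts use weighted k-means++ initial means; the
    restart with the highest log-likelihood wins, so the result is
    reproducible for a fixed seed.  Variances carry an additive
    regularisation of ``SD_FLOOR**2`` to keep components from collapsing
    on integer data, and convergence is declared when the log-likelihood
    improves by less than 1e-6 (500 iterations at most).
    """
    if n_components > hist.distinct:
        raise ValueError(
            f"n_components={n_components} exceeds {hist.distinct} distinct counts"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    values = np.array(sorted(hist.counts), dtype=float)
    weights = np.array([hist.counts[int(v)] for v in values], dtype=float)
    total = weights.sum()
    k, n_r = n_components, n_restarts
    reg = SD_FLOOR**2

    means = _kmeanspp_init(values, weights, k, n_r, rng)  # (R, K)
    # Initial variances and mixing weights from the hard assignment of each
    # histogram bin to its nearest seed mean (one k-means step): seeding
    # every component with the overall variance would make neighbouring
    # seeds share responsibilities immediately and collapse onto each
    # other, losing adjacent peaks.
    d2 = (values[None, None, :] - means[:, :, None]) ** 2  # (R, K, V)
    assign = np.argmin(d2, axis=1)  # (R, V)
    one_hot = assign[:, None, :] == np.arange(k)[None, :, None]  # (R, K, V)
    hard_w = one_hot * weights[None, None, :]
    nk0 = hard_w.sum(axis=2) + 1e-12
    means = (hard_w * values[None, None, :]).sum(axis=2) / nk0
    variances = (hard_w * (values[None, None, :] - means[:, :, None]) ** 2).sum(axis=2) / nk0 + reg
    mix = np.maximum(nk0, 1e-12)
    mix /= mix.sum(axis=1, keepdims=True)
    v = values[None, None, :]  # (1, 1, V)
    w = weights[None, :]       # (1, V)
    prev_ll = np.full(n_r, -np.inf)
    for _ in range(500):
        # E-step in log space: (R, K, V)
        log_prob = (
            -0.5 * ((v - means[:, :, None]) ** 2 / variances[:, :, None])
            - 0.5 * np.log(2.0 * np.pi * variances[:, :, None])
            + np.log(mix[:, :, None])
        )
        log_norm = logsumexp(log_prob, axis=1)  # (R, V)
        ll = (log_norm * w).sum(axis=1)  # (R,)
        resp = np.exp(log_prob - log_norm[:, None, :])  # (R, K, V)
        # M-step with histogram weights
        resp_w = resp * w[:, None, :]
        nk = resp_w.sum(axis=2) + 1e-12  # (R, K)
        means = (resp_w * v).sum(axis=2) / nk
        variances = (resp_w * (v - means[:, :, None]) ** 2).sum(axis=2) / nk + reg
        mix = nk / total
        if np.all(np.abs(ll - prev_ll) < 1e-6):
            break
        prev_ll = ll
    best = int(np.argmax(ll))
    order = np.argsort(means[best])
    b_means = means[best][order]
    b_sds = np.sqrt(variances[best][order])
    b_mix = mix[best][order]
    # hard assignment of each histogram bin to its maximum-responsibility
    # component
    labels = np.argmax(resp[best], axis=0)
    support = np.array(
        [int(weights[labels == orig].sum()) for orig in order]
    )
    loglik = float(ll[best])
    n_params = 3 * k - 1
    return GmmFit(
        n_components=k,
        means=b_means,
        sds=b_sds,
        weights=b_mix / b_mix.sum(),
        log_likelihood=loglik,
        aic=float(2 * n_params - 2 * loglik),
        support=support,
    )


def select_model(
    hist: CountHistogram,
    n_range: tuple[int, int] = (3, 7),
    n_restarts: int = 20,
    seed: int | np.random.Generator | None = 0,
) -> GmmFit:
    """AIC model selection over component counts with the interiority rule.

    Every feasible component count in ``n_range`` (inclusive) is fitted and
    the minimum-AIC fit is chosen; if the winner sits on an endpoint of the
    tried range, the best interior count is taken instead (with a warning),
    since an endpoint winner suggests the range should have been wider.  A
    single tried count is returned as-is.  When even the smallest requested
    count is infeasible, the largest feasible count is fitted as a
    degenerate fallback.
    """
    lo, hi = n_range
    if lo > hi:
        raise ValueError("invalid n_range")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    feasible = [n for n in range(lo, hi + 1) if n <= hist.distinct]
    if not feasible:
        fallback = hist.distinct
        logger.warning(
            "only %d distinct counts; falling back to a %d-component fit",
            hist.distinct,
            fallback,
        )
        return fit_gmm(hist, fallback, n_restarts=n_restarts, seed=rng)
    fits = {n: fit_gmm(hist, n, n_restarts=n_restarts, seed=rng) for n in feasible}
    best_n = min(fits, key=lambda n: fits[n].aic)
    if len(feasible) == 1:
        if feasible[0] in (lo, hi):
            logger.warning("single feasible component count %d (forced)", feasible[0])
        return fits[best_n]
    interior = [n for n in feasible if n not in (feasible[0], feasible[-1])]
    if best_n in (feasible[0], feasible[-1]) and interior:
        chosen = min(interior, key=lambda n: fits[n].aic)
        logger.warning(
            "AIC winner %d is an endpoint of %s; using best interior %d",
            best_n,
            feasible,
            chosen,
        )
        best_n = chosen
    return fits[best_n]


def call_alleles(
    fit: GmmFit, hist: CountHistogram, second_peak_ratio: float = 0.8
) -> AlleleCall:
    """Reduce a mixture fit to one or two allele calls.

    Components with no supporting reads are dropped; the retained set is
    the best-supported subset consistent with the ordering rule — of two
    components, the one with the smaller mean must have the smaller
    standard deviation and at least as many supporting reads.  (With at
    most seven components the maximal consistent subset is found by
    enumeration; greedy admission is order-sensitive and can let a noise
    shoulder evict a genuine far peak.)  The retained component with the
    most reads is the first peak; a second peak with a larger mean is
    accepted outright — the most distal one, since shoulders adjacent to
    the primary are splitting artifacts of one blob — while one with a
    smaller mean needs support above ``second_peak_ratio`` of the first
    peak's.
    """
    raw = sorted(
        (
            (float(fit.means[k]), float(fit.sds[k]), int(fit.support[k]))
            for k in range(fit.n_components)
            if fit.support[k] > 0
        ),
        key=lambda c: c[0],
    )
    # Sub-peaks of one wide allele blob are fused back into a single peak:
    # two components merge when their separation is small relative to their
    # spreads.  Two tight spikes one count apart (possible distinct alleles)
    # stay separate; the halves of a blob whose per-read noise spans several
    # counts do not.
    comps: list[tuple[float, float, int]] = []
    for mean, sd, support in raw:
        if comps:
            pm, psd, psup = comps[-1]
            if mean - pm <= 1.5 * (psd + sd):
                total = psup + support
                new_mean = (pm * psup + mean * support) / total
                # pooled second moment keeps the fused peak's true spread
                second = (
                    psup * (psd**2 + pm**2) + support * (sd**2 + mean**2)
                ) / total
                comps[-1] = (new_mean, float(np.sqrt(max(0.0, second - new_mean**2))), total)
                continue
        comps.append((mean, sd, support))
    def consistent(a: tuple[float, float, int], b: tuple[float, float, int]) -> bool:
        # The ordering rule — of two nearby components the one with the
        # smaller mean must have the smaller spread (relative tolerance)
        # and at least as many reads — separates a peak from its own noise
        # shoulders, so it applies locally (within two counts).  Across
        # distant peaks both component spread and component support reflect
        # how finely the mixture happened to split each blob, not read
        # noise, so distant pairs are never mutually exclusive; distant
        # junk is handled by the histogram-mass rules at the call stage.
        lo, hi = (a, b) if a[0] < b[0] else (b, a)
        if hi[0] - lo[0] > 2.0:
            return True
        if lo[1] > 1.3 * hi[1] + 0.05:
            return False
        if lo[2] < hi[2]:
            return False
        return True

    best_subset: tuple[int, ...] = ()
    best_key = (-1, 0)
    for mask in range(1, 1 << len(comps)):
        members = [k for k in range(len(comps)) if mask >> k & 1]
        if all(
            consistent(comps[i], comps[j])
            for x, i in enumerate(members)
            for j in members[x + 1 :]
        ):
            key = (sum(comps[k][2] for k in members), len(members))
            if key > best_key:
                best_key = key
                best_subset = tuple(members)
    retained = [comps[k] for k in best_subset]
    if not retained:  # cannot happen with nonzero support, but stay safe
        retained = comps

    def window(c: int) -> int:
        return sum(hist.counts.get(v, 0) for v in (c - 1, c, c + 1))

    def peak_window(comp: tuple[float, float, int]) -> int:
        # histogram mass within one count of the peak; a merged blob whose
        # mean landed between bins may take the better of the two flanking
        # centres, but a peak sitting on a bin must not peek at its
        # neighbour's mass
        mean = comp[0]
        centres = {round(mean)}
        if abs(mean - round(mean)) >= 0.3:
            centres.update((int(np.floor(mean)), int(np.ceil(mean))))
        return max(window(v) for v in centres)

    def bin_reads(comp: tuple[float, float, int]) -> int:
        return hist.counts.get(round(comp[0]), 0) or comp[2]

    primary = max(retained, key=lambda c: (peak_window(c), c[2], -c[0]))
    count1 = max(1, round(primary[0]))
    others = [c for c in retained if c is not primary and round(c[0]) != count1]
    second: tuple[float, float, int] | None = None
    # A peak two or more counts above the primary is a distinct expanded
    # allele, accepted when the histogram mass within one count of it
    # clears a noise floor (3.5% of informative reads: the rarest real
    # minority allele still carries about 5% under the coverage-allocation
    # rule, while stray tail mass stays near 2%).  A peak only one count
    # above the primary is indistinguishable from a splitting artifact of
    # the primary's own blob unless its bin rivals the primary's bin, so it
    # must clear the same support ratio as a smaller-count peak.
    def distal_mass(comp: tuple[float, float, int]) -> int:
        # mass within one count of the peak, excluding bins that belong to
        # the primary's own neighbourhood — a component parked just past
        # the primary blob must not borrow the blob's reads
        c = round(comp[0])
        return sum(
            hist.counts.get(v, 0) for v in (c - 1, c, c + 1) if v > count1 + 1
        )

    def rises_after_valley(comp: tuple[float, float, int]) -> bool:
        # a genuine second allele is a local maximum beyond a dip in the
        # histogram; a monotone decay from the primary blob is its tail
        c = round(comp[0])
        between = [hist.counts.get(v, 0) for v in range(count1 + 1, c)]
        own = hist.counts.get(c, 0)
        return own > 0 and (not between or min(between) < own)

    distal = [
        c
        for c in others
        if round(c[0]) >= count1 + 2
        and distal_mass(c) >= 0.035 * hist.total_reads
        and rises_after_valley(c)
    ]
    adjacent = [c for c in others if round(c[0]) == count1 + 1]
    if distal:
        second = max(distal, key=lambda c: (distal_mass(c), c[2], c[0]))
    elif adjacent and max(bin_reads(c) for c in adjacent) >= (
        second_peak_ratio * bin_reads(primary)
    ):
        second = max(adjacent, key=bin_reads)
    else:
        for cand in sorted(others, key=lambda c: -bin_reads(c)):
            if cand[0] < primary[0] and bin_reads(cand) >= (
                second_peak_ratio * bin_reads(primary)
            ):
                second = cand
                break
    if second is None:
        support = bin_reads(primary)
        return AlleleCall(count1, count1, support, support, "homozygous")
    count2 = max(1, round(second[0]))
    (a1, s1), (a2, s2) = sorted(
        [(count1, bin_reads(primary)), (count2, bin_reads(second))],
        key=lambda t: t[0],
    )
    return AlleleCall(a1, a2, s1, s2, "heterozygous")


def call_from_counts(
    raw: list[int],
    min_count: int = 5,
    min_reads: int = 3,
    n_range: tuple[int, int] = (3, 7),
    n_restarts: int = 20,
    second_peak_ratio: float = 0.8,
    seed: int | np.random.Generator | None = 0,
) -> AlleleCall:
    """Full filtering + model selection + allele calling convenience path."""
    hist = filter_counts(raw, min_count=min_count, min_reads=min_reads)
    if hist.distinct == 1:
        value = next(iter(hist.counts))
        n = hist.counts[value]
        return AlleleCall(value, value, n, n, "homozygous")
    fit = select_model(hist, n_range=n_range, n_restarts=n_restarts, seed=seed)
    return call_alleles(fit, hist, second_peak_ratio=second_peak_ratio)
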