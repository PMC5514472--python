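import numpy as np
import pytest

from tandemhmm.peak_calling import (
    AlleleCall,
    CountHistogram,
    GmmFit,
    NoInformativeReadsError,
    call_alleles,
    call_from_counts,
    filter_counts,
    fit_gmm,
    select_model,
)


def make_fit(components):
    """GmmFit from (mean, sd, support) triples, weights by support."""
    means = np.array([c[0] for c in components], dtype=float)
    sds = np.array([c[1] for c in components], dtype=float)
    support = np.array([c[2] for c in components])
    weights = support / support.sum()
    return GmmFit(
        n_components=len(components),
        means=means,
        sds=sds,
        weights=weights,
        log_likelihood=0.0,
        aic=0.0,
        support=support,
    )


def hist_from(counts):
    return CountHistogram(counts=dict(counts), total_reads=sum(counts.values()))


class TestFilterCounts:
    def test_default_minimum_count(self):
        hist = filter_counts([2, 3, 14, 14, 14])
        assert hist.counts == {14: 3}
        assert hist.total_reads == 3

    def test_low_support_bins_pruned(self):
        hist = filter_counts([14] * 5 + [40], min_reads=2)
        assert hist.counts == {14: 5}

    def test_everything_filtered_raises(self):
        with pytest.raises(NoInformativeReadsError):
            filter_counts([1, 2, 3, 4])
        with pytest.raises(NoInformativeReadsError):
            filter_counts([])


class TestFitGmm:
    def test_two_separated_clusters_recovered(self, rng):
        data = np.concatenate([rng.normal(20, 1, 100), rng.normal(67, 1, 100)])
        counts = np.clip(np.rint(data).astype(int), 1, None)
        hist = filter_counts(list(counts), min_reads=1)
        fit = fit_gmm(hist, 2, seed=0)
        means = np.sort(fit.means)
        assert means[0] == pytest.approx(20, abs=1)
        assert means[1] == pytest.approx(67, abs=1)

    def test_single_value(self):
        fit = fit_gmm(hist_from({14: 30}), 1, seed=0)
        assert fit.means[0] == pytest.approx(14)

    def test_seeded_determinism(self):
        hist = hist_from({12: 20, 13: 30, 20: 25, 21: 10})
        a = fit_gmm(hist, 3, seed=7)
        b = fit_gmm(hist, 3, seed=7)
        assert np.allclose(a.means, b.means)
        assert a.log_likelihood == b.log_likelihood

    def test_too_many_components(self):
        with pytest.raises(ValueError):
            fit_gmm(hist_from({14: 30}), 2)


class TestSelectModel:
    def test_bimodal_histogram_keeps_both_modes(self):
        hist = hist_from({19: 30, 20: 120, 21: 25, 66: 20, 67: 60, 68: 15})
        fit = select_model(hist, seed=0)
        # the two dominant components sit at the true allele counts
        top2 = np.argsort(fit.support)[-2:]
        assert sorted(np.rint(fit.means[top2]).astype(int)) == [20, 67]

    def test_forced_single_n_returned(self):
        hist = hist_from({10: 30, 11: 10, 30: 20})
        fit = select_model(hist, n_range=(3, 3), seed=0)
        assert fit.n_components == 3

    def test_unimodal_dominant_component(self):
        hist = hist_from({14: 200, 13: 10, 15: 8})
        fit = select_model(hist, seed=0)
        assert round(fit.means[np.argmax(fit.support)]) == 14


class TestCallAlleles:
    def test_single_peak_homozygous(self):
        fit = make_fit([(14, 0.3, 40)])
        call = call_alleles(fit, hist_from({14: 40}))
        assert call.alleles == (14, 14)
        assert call.zygosity == "homozygous"

    def test_larger_count_second_peak_accepted(self):
        fit = make_fit([(20, 0.5, 300), (67, 1.2, 90)])
        call = call_alleles(fit, hist_from({20: 300, 67: 90}))
        assert call.alleles == (20, 67)
        assert call.zygosity == "heterozygous"
        assert (call.support1, call.support2) == (300, 90)

    def test_weak_smaller_peak_rejected(self):
        # a smaller-count peak with less support than the primary violates
        # the ordering rule outright and never becomes a second allele
        fit = make_fit([(15, 0.4, 100), (20, 0.5, 300)])
        call = call_alleles(fit, hist_from({15: 100, 20: 300}))
        assert call.alleles == (20, 20)
        assert call.zygosity == "homozygous"

    def test_strong_smaller_peak_becomes_primary(self):
        # with the support order reversed the smaller count is the primary
        # and the larger peak is accepted as the expanded allele
        fit = make_fit([(15, 0.4, 300), (20, 0.5, 120)])
        call = call_alleles(fit, hist_from({15: 300, 20: 120}))
        assert call.alleles == (15, 20)

    def test_adjacent_peak_held_to_ratio(self):
        fit = make_fit([(20, 0.3, 300), (21, 0.3, 60)])
        call = call_alleles(fit, hist_from({20: 300, 21: 60}))
        assert call.alleles == (20, 20)  # 60 < 0.8 * 300
        fit = make_fit([(20, 0.3, 300), (21, 0.3, 280)])
        call = call_alleles(fit, hist_from({20: 300, 21: 280}))
        assert call.alleles == (20, 21)

    def test_ordering_rule_drops_noise_shoulder(self):
        # wide low-support shoulder left of the main peak violates the rule
        fit = make_fit([(25, 1.5, 15), (29, 0.5, 60), (82, 1.0, 20)])
        call = call_alleles(fit, hist_from({25: 15, 29: 60, 82: 20}))
        assert call.alleles == (29, 82)

    def test_allele_invariants(self):
        with pytest.raises(ValueError):
            AlleleCall(20, 15, 10, 10, "heterozygous")


class TestCallFromCounts:
    def test_homozygous_shortcut(self):
        call = call_from_counts([14] * 30)
        assert call.alleles == (14, 14)

    def test_two_spike_histogram(self):
        call = call_from_counts([20] * 120 + [67] * 40, seed=0)
        assert call.alleles == (20, 67)

    def test_recovery_rate_on_synthetic_mixtures(self):
        # two Gaussians, means >=5 apart, >=100 reads each: both means
        # recovered within +-1 in at least 95% of seeds
        ok = 0
        n_seeds = 20
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            mu1 = int(r.integers(10, 30))
            mu2 = mu1 + int(r.integers(5, 40))
            counts = np.concatenate(
                [np.rint(r.normal(mu1, 1, 120)), np.rint(r.normal(mu2, 1, 100))]
            ).astype(int)
            call = call_from_counts(list(counts), seed=seed)
            if abs(call.allele1 - mu1) <= 1 and abs(call.allele2 - mu2) <= 1:
                ok += 1
        assert ok >= int(0.95 * n_seeds)

    def test_equal_alleles_with_small_noise_called_homozygous(self):
        r = np.random.default_rng(0)
        counts = np.rint(r.normal(22, 0.8, 300)).astype(int)
        call = call_from_counts(list(counts), seed=0)
        assert call.zygosity == "homozygous"
        assert call.allele1 == 22
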