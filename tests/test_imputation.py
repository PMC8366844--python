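"""Imputation schemes, bin distributions, replicate pooling."""

import numpy as np
import pytest
from scipy import stats

from plantocc.imputation import (
    PosteriorBinDistribution,
    _impute_count,
    bin_posterior,
    bin_posteriors_for_mentioned,
    impute_from_posterior,
    impute_random,
    replicate_fit_and_pool,
)
from plantocc.models import MCMCConfig, build_model1
from plantocc.nuts import ModelFit, fit as nuts_fit, thin
from conftest import make_record


def mentioned_records(n, N=100):
    return [
        make_record(record_id=f"m{i}", species_id="spA", N=N, y=None, mentioned=True)
        for i in range(n)
    ]


class TestImputeCount:
    def test_small_product_clamped_to_one(self):
        assert _impute_count(0.01, 10) == 1  # round gives 0, clamp to 1

    def test_full_frequency_gives_sample_size(self):
        assert _impute_count(1.0, 17) == 17

    def test_round_half_up(self):
        assert _impute_count(0.25, 10) == 3  # 2.5 rounds up
        assert _impute_count(0.24, 10) == 2


class TestImputeRandom:
    def test_only_mentioned_rows_change(self, small_bundle):
        imputed = impute_random(small_bundle.records, seed=4)
        for orig, new in zip(small_bundle.records, imputed.records):
            if orig.mentioned:
                assert new.reported and 1 <= new.y <= new.N
            else:
                assert orig == new

    def test_no_mentioned_rows_warns_and_is_identity(self):
        recs = [make_record(y=3), make_record(record_id="r2", y=None)]
        with pytest.warns(UserWarning, match="no-op"):
            imputed = impute_random(recs, seed=1)
        assert imputed.records == recs

    def test_grid_values_uniform_by_chi_square(self):
        recs = mentioned_records(10_000, N=100)
        imputed = impute_random(recs, seed=77)
        y = np.array([r.y for r in imputed.records])
        # with N=100 the grid 0.01..1.00 maps bijectively onto y = 1..100
        counts = np.bincount(y, minlength=101)[1:]
        chi2, pval = stats.chisquare(counts)
        assert pval > 0.01

    def test_bounds_hold_on_ten_thousand_draws(self):
        rng_n = np.random.default_rng(5)
        recs = [
            make_record(record_id=f"m{i}", N=int(n), y=None, mentioned=True)
            for i, n in enumerate(rng_n.integers(1, 500, size=10_000))
        ]
        imputed = impute_random(recs, seed=6)
        for r in imputed.records:
            assert 1 <= r.y <= r.N


class TestBinPosterior:
    def _fit_with_p(self, p_draws):
        p = np.asarray(p_draws)[None, :, None].repeat(2, axis=0)
        return ModelFit(
            draws={"p": p},
            config=MCMCConfig(iterations=p.shape[1] + 1, warmup=1, chains=2),
        )

    def test_point_mass_yields_single_bin(self):
        fit = self._fit_with_p(np.full(500, 0.503))
        bins = bin_posterior(fit, 0, bin_width=0.01)
        assert np.count_nonzero(bins.bin_probabilities) == 1
        assert bins.bin_probabilities.sum() == pytest.approx(1.0)
        top = bins.midpoints[np.argmax(bins.bin_probabilities)]
        assert top == pytest.approx(0.505, abs=1e-12)

    def test_uniform_draws_spread_over_bins(self, rng):
        fit = self._fit_with_p(rng.uniform(0.011, 1.0, size=20_000))
        bins = bin_posterior(fit, 0, bin_width=0.01)
        nonzero = bins.bin_probabilities[bins.bin_probabilities > 0]
        assert len(nonzero) >= 95
        assert nonzero.max() < 0.03

    def test_zero_bin_excluded(self, rng):
        draws = np.concatenate([np.full(100, 0.004), np.full(100, 0.55)])
        fit = self._fit_with_p(draws)
        bins = bin_posterior(fit, 0, bin_width=0.01)
        # mass at 0.004 sits in the zero bin and is discarded
        assert bins.bin_probabilities.max() == pytest.approx(1.0)
        top_mid = bins.midpoints[np.argmax(bins.bin_probabilities)]
        assert 0.54 < top_mid < 0.56

    def test_all_draws_in_zero_bin_rejected(self):
        fit = self._fit_with_p(np.full(300, 0.001))
        with pytest.raises(ValueError, match="zero bin"):
            bin_posterior(fit, 0, bin_width=0.01)

    def test_probabilities_sum_to_one(self, rng):
        fit = self._fit_with_p(rng.beta(2, 5, size=5_000))
        bins = bin_posterior(fit, 0, bin_width=0.005)
        assert bins.bin_probabilities.sum() == pytest.approx(1.0, abs=1e-12)


class TestImputeFromPosterior:
    def test_single_bin_is_deterministic(self):
        recs = mentioned_records(1, N=20)
        edges = np.linspace(0, 1, 101)
        probs = np.zeros(100)
        probs[10] = 1.0  # bin (0.10, 0.11], midpoint 0.105
        bins = {"m0": PosteriorBinDistribution(edges, probs)}
        imputed = impute_from_posterior(recs, bins, seed=3)
        assert imputed.records[0].y == 2  # round(0.105 * 20) = 2

    def test_missing_bins_rejected(self):
        recs = mentioned_records(2)
        edges = np.linspace(0, 1, 101)
        probs = np.zeros(100)
        probs[50] = 1.0
        with pytest.raises(ValueError, match="m1"):
            impute_from_posterior(recs, {"m0": PosteriorBinDistribution(edges, probs)},
                                  seed=1)

    def test_seed_fixed_reproducibility(self, rng):
        recs = mentioned_records(50)
        edges = np.linspace(0, 1, 101)
        probs = np.full(100, 0.0)
        probs[20:40] = 1 / 20
        bins = {r.record_id: PosteriorBinDistribution(edges, probs) for r in recs}
        a = impute_from_posterior(recs, bins, seed=9)
        b = impute_from_posterior(recs, bins, seed=9)
        assert a.records == b.records

    def test_sampled_frequencies_match_bin_distribution(self):
        edges = np.linspace(0, 1, 101)
        probs = np.zeros(100)
        probs[10] = 0.5
        probs[30] = 0.3
        probs[60] = 0.2
        dist = PosteriorBinDistribution(edges, probs)
        rng = np.random.default_rng(11)
        draws = np.array([dist.sample(rng) for _ in range(10_000)])
        emp = {m: np.mean(draws == m) for m in dist.midpoints[[10, 30, 60]]}
        for m, p_true in zip(dist.midpoints[[10, 30, 60]], [0.5, 0.3, 0.2]):
            assert emp[m] == pytest.approx(p_true, abs=0.02)
        # empirical CDF against the discrete CDF
        cdf_true = np.cumsum(probs)
        cdf_emp = np.array([np.mean(draws <= e) for e in edges[1:]])
        assert np.abs(cdf_emp - cdf_true).max() < 0.02


def records_for_pooling(with_mentioned=True):
    recs = [
        make_record(record_id=f"r{i}", species_id="spA", N=30, y=y)
        for i, y in enumerate([3, 5, 2, 8])
    ]
    recs += [
        make_record(record_id=f"u{i}", species_id="spB", N=25,
                    y=(7 if i % 2 else None))
        for i in range(4)
    ]
    if with_mentioned:
        recs.append(make_record(record_id="m0", species_id="spB", N=40,
                                y=None, mentioned=True))
    return recs


@pytest.fixture(scope="module")
def psi_source_fit():
    recs = records_for_pooling()
    model = build_model1(recs)
    return nuts_fit(model, MCMCConfig(chains=2, iterations=600, warmup=300, seed=21),
                    compute_diagnostics=False)


class TestReplicateFitAndPool:
    def _pool(self, psi_source, n_replicates, method="random", seed=31):
        recs = records_for_pooling()
        config = MCMCConfig(chains=2, iterations=400, warmup=300, seed=seed)
        return replicate_fit_and_pool(
            recs,
            lambda r: build_model1(r, include_psi=False),
            method=method,
            config=config,
            psi_source=psi_source,
            n_replicates=n_replicates,
            bin_width=0.01,
        )

    def test_single_replicate_equals_its_thinned_fit(self, psi_source_fit):
        pooled = self._pool(psi_source_fit, n_replicates=1)
        # reproduce the replicate by hand with the same derived seeds
        master = np.random.SeedSequence(31)
        stream = master.spawn(1)[0]
        state = stream.generate_state(2)
        imputed = impute_random(records_for_pooling(), seed=int(state[0] % 2**31))
        model = build_model1(imputed.records, include_psi=False)
        rep = nuts_fit(
            model,
            MCMCConfig(chains=2, iterations=400, warmup=300,
                       seed=int(state[1] % 2**31)),
        )
        rep = thin(rep, 0.5)
        assert np.array_equal(pooled.draws["alpha"], rep.draws["alpha"])

    def test_pooled_draw_count_is_sum_of_replicates(self, psi_source_fit):
        pooled = self._pool(psi_source_fit, n_replicates=3)
        per_rep = (400 - 300) // 2
        assert pooled.n_draws == 3 * per_rep
        assert "psi" in pooled.draws

    def test_pooled_mean_is_mean_of_replicate_means(self, psi_source_fit):
        pooled = self._pool(psi_source_fit, n_replicates=3)
        alpha = pooled.draws["alpha"]  # (chains, 3*m, J)
        m = alpha.shape[1] // 3
        rep_means = [alpha[:, k * m : (k + 1) * m].mean() for k in range(3)]
        assert alpha.mean() == pytest.approx(np.mean(rep_means), abs=1e-12)

    def test_posterior_method_runs_and_respects_bounds(self, psi_source_fit):
        pooled = self._pool(psi_source_fit, n_replicates=2, method="posterior")
        assert pooled.meta["method"] == "posterior"
        assert len(pooled.diagnostics["replicates"]) == 2

    def test_psi_draws_come_from_source_posterior(self, psi_source_fit):
        pooled = self._pool(psi_source_fit, n_replicates=2)
        source_vals = set(psi_source_fit.stacked("psi")[:, 0])
        assert set(pooled.stacked("psi")[:, 0]) <= source_vals

    def test_requires_psi_source(self):
        with pytest.raises(ValueError, match="psi_source"):
            replicate_fit_and_pool(
                records_for_pooling(),
                lambda r: build_model1(r, include_psi=False),
                method="random",
                config=MCMCConfig(chains=2, iterations=400, warmup=300, seed=1),
            )

    def test_unknown_method_rejected(self, psi_source_fit):
        with pytest.raises(ValueError, match="method"):
            self._pool(psi_source_fit, 1, method="magic")


def test_posterior_bins_per_mentioned_record(psi_source_fit):
    recs = records_for_pooling()
    bins = bin_posteriors_for_mentioned(recs, psi_source_fit, bin_width=0.01)
    assert set(bins) == {"m0"}
    assert bins["m0"].bin_probabilities.sum() == pytest.approx(1.0)
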