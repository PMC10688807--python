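import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import spearmanr

from bifidopart.diffabund import (
    bh_adjust,
    nb_lrt_global,
    nb_wald_pairwise,
    poscounts_size_factors,
    results_to_frame,
)


def _bh_oracle(p):
    """Literal BH definition: sort, p*m/i, cumulative min from the largest."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


class TestBHAdjust:
    def test_uniform_ladder(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_matches_brute_force_definition(self, rng):
        p = rng.random(100)
        assert np.allclose(bh_adjust(p), _bh_oracle(p), atol=0)

    def test_cross_check_against_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(50)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_adjust(p), q_sm)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_nan_propagates_and_family_shrinks(self):
        q = bh_adjust([0.05, np.nan])
        assert q[0] == pytest.approx(0.05)  # m = 1
        assert np.isnan(q[1])


class TestPoscounts:
    def test_exact_proportionality(self):
        counts = pd.DataFrame({"s1": [10, 30], "s2": [20, 60]}, index=["a", "b"])
        sf = poscounts_size_factors(counts)
        assert sf["s2"] / sf["s1"] == pytest.approx(2.0, rel=1e-12)

    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame({"s1": [5, 0, 7], "s2": [5, 0, 7]}, index=list("abc"))
        sf = poscounts_size_factors(counts)
        assert np.allclose(sf, 1.0)

    def test_factors_multiply_to_one(self, rng):
        counts = pd.DataFrame(rng.integers(0, 50, (20, 10)) * (rng.random((20, 10)) > 0.4))
        counts.iloc[0] += 1  # keep every sample non-empty
        sf = poscounts_size_factors(counts)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0, rel=1e-12)

    def test_matches_literal_definition_oracle(self, rng):
        X = (rng.integers(1, 60, (20, 10)) * (rng.random((20, 10)) > 0.45)).astype(float)
        X[0] += 1
        counts = pd.DataFrame(X)
        # independent literal implementation
        n = X.shape[1]
        r = np.array([np.exp(sum(np.log(x) for x in row if x > 0) / n) for row in X])
        s = np.array(
            [
                np.median([X[i, j] / r[i] for i in range(X.shape[0]) if r[i] > 0 and X[i, j] > 0])
                for j in range(n)
            ]
        )
        s = s / np.exp(np.mean(np.log(s)))
        assert np.allclose(poscounts_size_factors(counts).to_numpy(), s, atol=1e-12)

    def test_scaling_one_sample_scales_its_factor(self):
        counts = pd.DataFrame(
            {"s1": [10, 20, 5], "s2": [12, 18, 6], "s3": [9, 22, 4]}, index=list("abc")
        )
        sf1 = poscounts_size_factors(counts)
        scaled = counts.copy()
        scaled["s3"] = scaled["s3"] * 3
        sf2 = poscounts_size_factors(scaled)
        assert (sf2["s3"] / sf2["s1"]) / (sf1["s3"] / sf1["s1"]) == pytest.approx(3.0, rel=1e-9)

    def test_all_zero_sample_errors(self):
        counts = pd.DataFrame({"s1": [1, 2], "s2": [0, 0]})
        with pytest.raises(ValueError):
            poscounts_size_factors(counts)


def _nb_counts(rng, mu, alpha, n):
    # NB2 with mean mu, variance mu + alpha mu^2 via gamma-Poisson
    shape = 1.0 / alpha
    lam = rng.gamma(shape, mu / shape, size=n)
    return rng.poisson(lam)


class TestWaldPairwise:
    def test_identical_groups_zero_log2fc(self):
        vals = [8, 12, 30, 4, 19, 7]
        counts = pd.DataFrame(
            {f"a{i}": vals for i in range(4)} | {f"b{i}": vals for i in range(4)},
            index=[f"t{i}" for i in range(6)],
        )
        sf = pd.Series(1.0, index=counts.columns)
        groups = {c: c[0] for c in counts.columns}
        res = nb_wald_pairwise(counts, sf, groups, ("a", "b"))
        for r in res:
            assert abs(r.log2fc) < 1e-6

    def test_planted_log2fc_recovered(self):
        rng = np.random.default_rng(0)
        n = 200
        taxa = {}
        for t in range(10):
            mu = rng.uniform(50, 200)
            a = np.concatenate(
                [_nb_counts(rng, mu, 0.1, n), _nb_counts(rng, mu * (4 if t == 0 else 1), 0.1, n)]
            )
            taxa[f"t{t}"] = a
        counts = pd.DataFrame(taxa).T
        counts.columns = [f"A{i}" for i in range(n)] + [f"B{i}" for i in range(n)]
        sf = pd.Series(1.0, index=counts.columns)
        groups = {c: c[0] for c in counts.columns}
        res = {r.taxon: r for r in nb_wald_pairwise(counts, sf, groups, ("B", "A"))}
        assert abs(res["t0"].log2fc - 2.0) < 0.5
        assert res["t0"].q < 0.05
        for t in range(1, 10):
            assert abs(res[f"t{t}"].log2fc) < 0.5

    def test_type_i_error_rate(self):
        rng = np.random.default_rng(1)
        n = 50
        counts = pd.DataFrame(
            {f"s{j}": _nb_counts(rng, 100, 0.2, 1000) for j in range(2 * n)},
            index=[f"t{i}" for i in range(1000)],
        )
        sf = pd.Series(1.0, index=counts.columns)
        groups = {f"s{j}": ("A" if j < n else "B") for j in range(2 * n)}
        res = nb_wald_pairwise(counts, sf, groups, ("A", "B"))
        ps = np.array([r.p for r in res])
        frac = (ps < 0.05).mean()
        assert abs(frac - 0.05) < 0.02

    def test_all_zero_taxon_untestable(self):
        counts = pd.DataFrame(
            {"a1": [0, 5], "a2": [0, 8], "b1": [0, 6], "b2": [0, 9]}, index=["z", "t"]
        )
        sf = pd.Series(1.0, index=counts.columns)
        groups = {c: c[0] for c in counts.columns}
        res = {r.taxon: r for r in nb_wald_pairwise(counts, sf, groups, ("a", "b"))}
        assert not res["z"].testable and np.isnan(res["z"].p)
        assert res["t"].testable

    def test_removing_other_taxa_does_not_change_statistics(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.poisson(40, (8, 12)), index=[f"t{i}" for i in range(8)], columns=[f"s{j}" for j in range(12)]
        )
        sf = poscounts_size_factors(counts)
        groups = {f"s{j}": ("A" if j < 6 else "B") for j in range(12)}
        full = results_to_frame(nb_wald_pairwise(counts, sf, groups, ("A", "B")))
        subset = results_to_frame(nb_wald_pairwise(counts.iloc[2:], sf, groups, ("A", "B")))
        merged = full[full.taxon.isin(subset.taxon)].reset_index(drop=True)
        assert np.allclose(merged["stat"], subset["stat"], equal_nan=True)


class TestLRTGlobal:
    @staticmethod
    def _nb_loglik(y, mu, alpha):
        # NB2 log-likelihood, written independently of statsmodels
        r = 1.0 / alpha
        return float(
            np.sum(
                gammaln(y + r)
                - gammaln(r)
                - gammaln(y + 1)
                + r * np.log(r / (r + mu))
                + y * np.log(mu / (r + mu))
            )
        )

    def test_identical_groups_statistic_zero(self):
        vals = [3, 14, 9, 6]
        counts = pd.DataFrame({f"{g}{i}": vals for g in "abc" for i in range(3)}, index=list("wxyz"))
        sf = pd.Series(1.0, index=counts.columns)
        groups = {c: c[0] for c in counts.columns}
        res = nb_lrt_global(counts, sf, groups)
        for r in res:
            assert r.stat < 1e-6
            assert r.p > 0.999

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(5)
        n = 60
        taxa = {}
        for t in range(8):
            mu = 80.0
            y = np.concatenate(
                [
                    _nb_counts(rng, mu * (4 if t == 0 else 1), 0.1, n),
                    _nb_counts(rng, mu, 0.1, n),
                    _nb_counts(rng, mu, 0.1, n),
                ]
            )
            taxa[f"t{t}"] = y
        counts = pd.DataFrame(taxa).T
        counts.columns = [f"{g}{i}" for g in "ABC" for i in range(n)]
        sf = pd.Series(1.0, index=counts.columns)
        groups = {c: c[0] for c in counts.columns}
        res = {r.taxon: r for r in nb_lrt_global(counts, sf, groups)}
        assert res["t0"].q < 0.05

    def test_statistic_matches_independent_loglik_oracle(self):
        rng = np.random.default_rng(6)
        y = np.concatenate([rng.poisson(30, 10), rng.poisson(70, 10), rng.poisson(45, 10)])
        counts = pd.DataFrame([y], index=["t"], columns=[f"{g}{i}" for g in "ABC" for i in range(10)])
        sf = pd.Series(1.0, index=counts.columns)
        groups = {c: c[0] for c in counts.columns}
        res = nb_lrt_global(counts, sf, groups)[0]
        alpha = res.dispersion

        # oracle: 1-D maximisations of the independent NB log-likelihood
        def best_ll(sub):
            f = lambda logm: -self._nb_loglik(sub, np.exp(logm), alpha)  # noqa: E731
            opt = minimize_scalar(f, bounds=(-5, 15), method="bounded", options={"xatol": 1e-12})
            return -opt.fun

        ll_full = sum(best_ll(y[i * 10 : (i + 1) * 10]) for i in range(3))
        ll_null = best_ll(y)
        assert res.stat == pytest.approx(2 * (ll_full - ll_null), abs=1e-6)

    def test_fewer_than_three_groups_errors(self):
        counts = pd.DataFrame({"a1": [1], "b1": [2]}, index=["t"])
        sf = pd.Series(1.0, index=counts.columns)
        with pytest.raises(ValueError):
            nb_lrt_global(counts, sf, {"a1": "a", "b1": "b"})

    def test_wald_and_lrt_rank_agreement(self):
        rng = np.random.default_rng(7)
        n = 80
        taxa = {}
        effects = rng.uniform(0, 1.5, 60)
        for t in range(60):
            mu = 60.0
            y = np.concatenate(
                [
                    _nb_counts(rng, mu * 2 ** effects[t], 0.1, n),
                    _nb_counts(rng, mu, 0.1, n),
                    _nb_counts(rng, mu, 0.1, n),
                ]
            )
            taxa[f"t{t}"] = y
        counts = pd.DataFrame(taxa).T
        counts.columns = [f"{g}{i}" for g in "ABC" for i in range(n)]
        sf = pd.Series(1.0, index=counts.columns)
        groups = {c: c[0] for c in counts.columns}
        lrt = np.array([r.p for r in nb_lrt_global(counts, sf, groups)])
        wald = np.array([r.p for r in nb_wald_pairwise(counts, sf, groups, ("A", "B"))])
        rho, _ = spearmanr(lrt, wald)
        assert rho > 0.9
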