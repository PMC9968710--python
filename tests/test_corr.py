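import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methconcord import corr
from methconcord.synth import SimulationConfig, generate_cohort
from methconcord.types import MultiTissueDataset


def _beta(values, probes=None, subjects=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    probes = probes or [f"cg{i}" for i in range(values.shape[0])]
    subjects = subjects or [f"S{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=probes, columns=subjects)


class TestWithinSubject:
    def test_monotone_increasing_pair_rho_one(self):
        x = np.arange(19) / 19
        y = np.arange(19) ** 2 / 400
        rec = corr.within_subject_cpg_correlation(_beta(x), _beta(y))
        assert rec["rho"].iloc[0] == pytest.approx(1.0)

    def test_opposed_monotone_rho_minus_one(self):
        x = np.arange(19) / 19
        rec = corr.within_subject_cpg_correlation(_beta(x), _beta(1 - x))
        assert rec["rho"].iloc[0] == pytest.approx(-1.0)

    def test_exact_p_matches_enumeration_oracle(self, rng):
        # brute-force oracle written here, independent of the engine
        for _ in range(5):
            n = 7
            x = rng.random(n)
            y = rng.random(n)
            rec = corr.within_subject_cpg_correlation(_beta(x), _beta(y))
            rho_obs, p_obs = rec["rho"].iloc[0], rec["p"].iloc[0]
            rx = stats.rankdata(x)
            count = 0
            total = 0
            for perm in itertools.permutations(stats.rankdata(y)):
                r = np.corrcoef(rx, perm)[0, 1]
                if abs(r) >= abs(rho_obs) - 1e-9:
                    count += 1
                total += 1
            assert p_obs == pytest.approx(count / total, abs=1e-12)

    def test_ties_use_t_approximation(self):
        x = np.array([0.1, 0.1, 0.3, 0.4, 0.5, 0.6])
        y = np.array([0.2, 0.3, 0.1, 0.5, 0.4, 0.6])
        rec = corr.within_subject_cpg_correlation(_beta(x), _beta(y))
        expected = corr.t_approximation_p(rec["rho"].iloc[0], 6)
        assert rec["p"].iloc[0] == pytest.approx(float(expected))

    def test_constant_vector_zero_variance_reason(self):
        x = np.full(10, 0.5)
        y = np.arange(10) / 10
        rec = corr.within_subject_cpg_correlation(_beta(x), _beta(y))
        assert np.isnan(rec["rho"].iloc[0])
        assert rec["reason_code"].iloc[0] == corr.REASON_ZERO_VARIANCE

    def test_min_n_guard(self):
        x = np.array([0.1, 0.2, np.nan, np.nan, np.nan, np.nan])
        y = np.array([0.2, 0.1, 0.3, 0.4, 0.5, 0.6])
        rec = corr.within_subject_cpg_correlation(_beta(x), _beta(y), min_n=5)
        assert rec["reason_code"].iloc[0] == corr.REASON_INSUFFICIENT_N
        assert np.isnan(rec["rho"].iloc[0])

    def test_pairwise_complete_matches_scipy(self, rng):
        x = rng.random(15)
        y = rng.random(15)
        x[[2, 9]] = np.nan
        rec = corr.within_subject_cpg_correlation(_beta(x), _beta(y))
        mask = ~np.isnan(x)
        expected = stats.spearmanr(x[mask], y[mask]).statistic
        assert rec["rho"].iloc[0] == pytest.approx(expected)
        assert rec["n_used"].iloc[0] == 13

    def test_monotone_transform_invariance(self, rng):
        x = rng.random(19)
        y = rng.random(19)
        base = corr.within_subject_cpg_correlation(_beta(x), _beta(y))
        for fx, fy in [(np.exp, np.cbrt), (lambda v: v ** 3, np.exp)]:
            rec = corr.within_subject_cpg_correlation(_beta(fx(x)), _beta(fy(y)))
            assert rec["rho"].iloc[0] == pytest.approx(base["rho"].iloc[0])
            assert rec["p"].iloc[0] == pytest.approx(base["p"].iloc[0])

    def test_matches_scipy_spearman_vectorized(self, rng):
        A = rng.random((50, 19))
        B = rng.random((50, 19))
        rec = corr.within_subject_cpg_correlation(_beta(A), _beta(B))
        for i in range(50):
            res = stats.spearmanr(A[i], B[i])
            assert rec["rho"].iloc[i] == pytest.approx(res.statistic)
            assert rec["p"].iloc[i] == pytest.approx(res.pvalue, abs=1e-12)


class TestCriticalRho:
    def test_n19_rounds_to_046(self):
        assert corr.critical_rho(19, 0.05).rounded == pytest.approx(0.46)

    def test_alpha_near_one_threshold_near_zero(self):
        assert corr.critical_rho(19, 0.999).exact < 0.01

    def test_bisection_oracle(self):
        # independent bisection on the p-value function
        n, alpha = 19, 0.05
        lo, hi = 0.0, 1.0 - 1e-9
        for _ in range(60):
            mid = (lo + hi) / 2
            if float(corr.t_approximation_p(np.array(mid), n)) < alpha:
                hi = mid
            else:
                lo = mid
        assert corr.critical_rho(n, alpha).exact == pytest.approx(hi, abs=1e-6)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            corr.critical_rho(19, alpha=1.5)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            corr.critical_rho(3)


class TestBHAdjust:
    def test_all_equal(self):
        q = corr.bh_adjust([0.03, 0.03, 0.03])
        assert np.allclose(q, 0.03)

    def test_worked_example(self):
        q = corr.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert corr.bh_adjust([0.2]) == pytest.approx([0.2])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.random(500)
        q = corr.bh_adjust(p)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_sm)

    def test_monotone_in_sorted_p(self, rng):
        p = rng.random(200)
        q = corr.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_never_fewer_rejections_than_bonferroni(self, rng):
        p = rng.random(300) ** 2
        q = corr.bh_adjust(p)
        alpha = 0.05
        bonf = (p < alpha / p.size).sum()
        assert (q < alpha).sum() >= bonf

    def test_nan_propagates(self):
        q = corr.bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1]) and np.isfinite(q[0])


class TestSummarize:
    def test_perfect_correlations(self):
        rec = pd.DataFrame({
            "probe_id": ["a", "b"], "tissue_pair": "x-y",
            "rho": [1.0, 1.0], "p": [1e-9, 1e-9], "q": [2e-9, 2e-9],
        })
        s = corr.summarize(rec)
        assert s.frac_nominal == 1.0 and s.frac_moderate == 1.0

    def test_counts_match_direct_filtering(self, rng):
        n = 500
        rho = rng.uniform(-1, 1, n)
        p = rng.random(n)
        rec = pd.DataFrame({"probe_id": [f"cg{i}" for i in range(n)],
                            "tissue_pair": "x-y", "rho": rho, "p": p,
                            "q": corr.bh_adjust(p)})
        s = corr.summarize(rec)
        assert s.frac_nominal == pytest.approx((p < 0.05).mean())
        assert s.frac_moderate == pytest.approx((rho > 0.5).mean())
        assert s.frac_moderate_negative == pytest.approx((rho < -0.5).mean())
        assert s.n_bh_significant == int((corr.bh_adjust(p) < 0.05).sum())

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            corr.summarize(pd.DataFrame(columns=["rho", "p", "q", "tissue_pair"]))


class TestAcrossSubject:
    def test_identical_matrices_r_one(self, rng):
        beta = _beta(rng.random((100, 8)))
        s = corr.across_subject_correlation(beta, beta)
        assert s.r == pytest.approx(1.0)

    def test_reversed_means_r_minus_one(self, rng):
        beta = _beta(rng.random((100, 8)))
        flipped = _beta(1 - beta.to_numpy(), probes=list(beta.index))
        s = corr.across_subject_correlation(beta, flipped)
        assert s.r == pytest.approx(-1.0)

    def test_matches_direct_formula(self, rng):
        a = _beta(rng.random((100, 6)))
        b = _beta(rng.random((100, 6)), probes=list(a.index))
        s = corr.across_subject_correlation(a, b)
        ma, mb = a.mean(axis=1).to_numpy(), b.mean(axis=1).to_numpy()
        cov = ((ma - ma.mean()) * (mb - mb.mean())).sum()
        expected = cov / np.sqrt(((ma - ma.mean()) ** 2).sum()
                                 * ((mb - mb.mean()) ** 2).sum())
        assert s.r == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_raises(self):
        a = _beta(np.full((10, 4), 0.5))
        b = _beta(np.random.default_rng(0).random((10, 4)),
                  probes=[f"cg{i}" for i in range(10)])
        with pytest.raises(ValueError):
            corr.across_subject_correlation(a, b)


class TestPerSubject:
    def _dataset(self, rng, n_probes=50, n_subjects=6):
        probes = [f"cg{i}" for i in range(n_probes)]
        subjects = [f"S{j}" for j in range(n_subjects)]
        betas = {t: pd.DataFrame(rng.random((n_probes, n_subjects)),
                                 index=probes, columns=subjects)
                 for t in ("brain", "blood")}
        return MultiTissueDataset(betas=betas)

    def test_identical_tissue_all_ones(self, rng):
        ds = self._dataset(rng)
        ds.betas["blood"] = ds.betas["brain"].copy()
        table = corr.per_subject_correlation(ds)
        assert np.allclose(table["blood-brain"], 1.0)
        r, p = corr.coupling(table.assign(other=1.0), "blood-brain", "other")
        assert np.isnan(r)

    def test_hand_computed_five_probes(self):
        a = _beta(np.array([[0.1, 0.9], [0.2, 0.8], [0.3, 0.4],
                            [0.7, 0.2], [0.5, 0.6]]), subjects=["S0", "S1"])
        b = _beta(np.array([[0.2, 0.8], [0.1, 0.9], [0.4, 0.3],
                            [0.6, 0.1], [0.5, 0.7]]),
                  probes=list(a.index), subjects=["S0", "S1"])
        ds = MultiTissueDataset(betas={"brain": a, "blood": b})
        table = corr.per_subject_correlation(ds)
        for j, subj in enumerate(["S0", "S1"]):
            expected = np.corrcoef(a.iloc[:, j], b.iloc[:, j])[0, 1]
            assert table.loc[subj, "blood-brain"] == pytest.approx(expected)

    def test_planted_coupling_sign_recovered(self):
        cfg = SimulationConfig(n_subjects=19, n_probes=1500,
                               frac_correlated=0.3, rho_true=0.8,
                               noise_sd=0.01, seed=77)
        ds, _ = generate_cohort(cfg)
        table = corr.per_subject_correlation(ds)
        r, p = corr.coupling(table, "brain-buccal", "blood-buccal")
        assert np.isfinite(r)


class TestMDS:
    def test_collinear_samples_exact_1d(self):
        t = np.linspace(0, 1, 6)
        X = pd.DataFrame(np.outer(t, np.ones(10) * 0.3) + 0.2)
        emb = corr.mds_embedding(X, k=1)
        d_emb = np.abs(emb["dim1"].to_numpy()[:, None]
                       - emb["dim1"].to_numpy()[None, :])
        d_true = np.sqrt(((X.to_numpy()[:, None, :]
                           - X.to_numpy()[None, :, :]) ** 2).sum(-1))
        assert np.allclose(d_emb, d_true, atol=1e-9)

    def test_two_clusters_separate_on_dim1(self, rng):
        a = rng.normal(0.2, 0.01, size=(8, 30))
        b = rng.normal(0.8, 0.01, size=(8, 30))
        X = pd.DataFrame(np.vstack([a, b]))
        emb = corr.mds_embedding(X, k=2)
        ca, cb = emb["dim1"][:8].mean(), emb["dim1"][8:].mean()
        spread = max(emb["dim1"][:8].std(), emb["dim1"][8:].std())
        assert abs(ca - cb) > 5 * spread

    def test_duplicate_samples_coincide(self, rng):
        base = rng.random((4, 20))
        X = pd.DataFrame(np.vstack([base, base[0]]))
        emb = corr.mds_embedding(X, k=2)
        assert np.allclose(emb.iloc[0], emb.iloc[4], atol=1e-9)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            corr.mds_embedding(pd.DataFrame(np.zeros((2, 5))))


class TestAncestryPCs:
    def _annotation(self, probes, proximal):
        return pd.DataFrame({
            "probe_id": probes,
            "snp_distance_bp": [0 if p in proximal else 100 for p in probes],
            "context": "cpg",
        })

    def test_two_populations_separate(self, rng):
        probes = [f"cg{i}" for i in range(40)]
        subjects = [f"S{j}" for j in range(12)]
        vals = np.empty((40, 12))
        vals[:, :6] = rng.choice([0.05, 0.5], size=(40, 6))
        vals[:, 6:] = rng.choice([0.5, 0.95], size=(40, 6))
        beta = pd.DataFrame(vals, index=probes, columns=subjects)
        ann = self._annotation(probes, set(probes[:30]))
        pcs = corr.ancestry_pcs(beta, ann, max_dist=0, k=2)
        g1, g2 = pcs["PC1"][:6], pcs["PC1"][6:]
        gap = abs(g1.mean() - g2.mean())
        assert gap > 2 * max(g1.std(), g2.std())

    def test_identical_subjects_zero_scores(self):
        probes = [f"cg{i}" for i in range(10)]
        beta = pd.DataFrame(np.tile(np.linspace(0.1, 0.9, 10)[:, None], (1, 6)),
                            index=probes, columns=[f"S{j}" for j in range(6)])
        ann = self._annotation(probes, set(probes))
        pcs = corr.ancestry_pcs(beta, ann, k=2)
        assert np.allclose(pcs.to_numpy(), 0.0, atol=1e-12)

    def test_svd_norm_completeness(self, rng):
        probes = [f"cg{i}" for i in range(30)]
        subjects = [f"S{j}" for j in range(8)]
        beta = pd.DataFrame(rng.random((30, 8)), index=probes, columns=subjects)
        ann = self._annotation(probes, set(probes))
        pcs = corr.ancestry_pcs(beta, ann, k=7)
        M = beta.to_numpy().T
        M = M - M.mean(axis=0, keepdims=True)
        assert np.square(pcs.to_numpy()).sum() == pytest.approx(
            np.square(M).sum(), abs=1e-9)

    def test_no_proximal_probes_raises(self, rng):
        probes = [f"cg{i}" for i in range(10)]
        beta = pd.DataFrame(rng.random((10, 6)), index=probes,
                            columns=[f"S{j}" for j in range(6)])
        ann = self._annotation(probes, set())
        with pytest.raises(ValueError):
            corr.ancestry_pcs(beta, ann)
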