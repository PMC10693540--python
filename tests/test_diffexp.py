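import numpy as np
import pandas as pd
import pytest
from scipy import stats

from toxsig.containers import CountMatrix
from toxsig.diffexp import (
    DEModel,
    bh_adjust,
    estimate_dispersion,
    significance_filter,
    size_factors,
)
from toxsig.errors import DesignError, ToxsigError

from conftest import make_cm, nb_counts


def brute_force_size_factors(K):
    """Independent median-of-ratios: explicit loops, no shared code.

    The median over genes of count / gene geometric mean, taken on the
    log scale (so an even count of genes averages the two middle ratios
    geometrically), rescaled to geometric mean one.
    """
    import math

    G, S = K.shape
    geo = []
    for i in range(G):
        if all(K[i, j] > 0 for j in range(S)):
            geo.append((i, math.exp(sum(math.log(K[i, j]) for j in range(S)) / S)))
    factors = []
    for j in range(S):
        ratios = sorted(K[i, j] / g for i, g in geo)
        m = len(ratios)
        med = (
            ratios[m // 2]
            if m % 2
            else math.sqrt(ratios[m // 2 - 1] * ratios[m // 2])
        )
        factors.append(med)
    gm = math.exp(sum(math.log(f) for f in factors) / S)
    return [f / gm for f in factors]


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = make_cm(np.tile([[5], [10], [20]], (1, 4)))
        assert np.allclose(size_factors(cm), 1.0)

    def test_doubled_column_doubles_its_factor(self):
        base = np.array([[5, 10], [10, 20], [20, 40]])
        sf = size_factors(make_cm(base))
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        r = np.random.default_rng(seed)
        K = r.poisson(r.lognormal(3, 1, (20, 1)) * r.uniform(0.5, 2, 6)) + 1
        sf = size_factors(make_cm(K))
        assert np.allclose(sf.to_numpy(), brute_force_size_factors(K), rtol=1e-12)

    def test_geometric_mean_is_one(self, rng):
        K = rng.poisson(50, (30, 5)) + 1
        sf = size_factors(make_cm(K))
        assert np.exp(np.log(sf).mean()) == pytest.approx(1.0, abs=1e-6)

    def test_no_allpositive_gene_advises_fallback(self):
        K = np.array([[0, 5], [5, 0]])
        with pytest.raises(ToxsigError, match="poscounts"):
            size_factors(make_cm(K))
        sf = size_factors(make_cm(K), method="poscounts")
        assert (sf > 0).all()


class TestEstimateDispersion:
    def _groups(self, n_per, k):
        return pd.Series(
            np.repeat([f"grp{i}" for i in range(k)], n_per),
            index=[f"s{j}" for j in range(n_per * k)],
        )

    def test_poisson_counts_give_near_zero_dispersion(self, rng):
        mu = rng.lognormal(5, 0.5, 500)
        K = np.column_stack([rng.poisson(mu) for _ in range(10)])
        cm = make_cm(K)
        sf = pd.Series(1.0, index=cm.sample_ids)
        disp = estimate_dispersion(cm, sf, self._groups(5, 2), shrinkage=0.0)
        assert disp.median() < 1e-2

    def test_nb_dispersion_recovered_with_many_replicates(self, rng):
        mu = rng.lognormal(5.5, 0.5, 400)
        K = nb_counts(rng, mu, 0.1, 50)
        cm = make_cm(K)
        sf = pd.Series(1.0, index=cm.sample_ids)
        disp = estimate_dispersion(cm, sf, self._groups(50, 1), shrinkage=0.0)
        assert 0.07 <= disp.median() <= 0.13

    def test_constant_counts_hit_floor(self):
        cm = make_cm(np.full((3, 4), 7))
        sf = pd.Series(1.0, index=cm.sample_ids)
        disp = estimate_dispersion(cm, sf, self._groups(2, 2))
        assert (disp <= 1e-6).all()

    def test_single_replicate_group_rejected(self):
        cm = make_cm(np.ones((3, 3), dtype=int))
        sf = pd.Series(1.0, index=cm.sample_ids)
        groups = pd.Series(["a", "a", "b"], index=cm.sample_ids)
        with pytest.raises(DesignError):
            estimate_dispersion(cm, sf, groups)


class TestNBWald:
    def _null_cm(self, rng, G=500, n=3, alpha=0.05):
        mu = rng.lognormal(5, 1, G)
        return make_cm(nb_counts(rng, mu, alpha, 2 * n)), n

    def test_identical_groups_give_zero_lfc(self, rng):
        K = nb_counts(rng, rng.lognormal(5, 1, 100), 0.05, 3)
        cm = make_cm(np.hstack([K, K]))  # second group duplicates the first
        res = DEModel(
            cm, None, ["s3", "s4", "s5"], ["s0", "s1", "s2"]
        ).fit()
        assert res.table["log2FoldChange"].abs().median() < 1e-6

    def test_null_simulation_pvalues_uniform(self, rng):
        cm, n = self._null_cm(rng)
        res = DEModel(
            cm, None, [f"s{j}" for j in range(n, 2 * n)], [f"s{j}" for j in range(n)]
        ).fit()
        p = res.table["pvalue"].dropna()
        assert stats.kstest(p, "uniform").pvalue > 1e-3

    def test_twofold_effect_recovered(self, rng):
        G, nresp, n, alpha = 1200, 150, 3, 0.01
        mu = rng.lognormal(5.5, 0.8, G)
        fc = np.ones(G)
        fc[:nresp] = 2.0
        Kc = nb_counts(rng, mu, alpha, n)
        Kt = nb_counts(rng, fc * mu, alpha, n)
        cm = make_cm(np.hstack([Kc, Kt]))
        res = DEModel(
            cm, None, [f"s{j}" for j in range(n, 2 * n)], [f"s{j}" for j in range(n)]
        ).fit()
        mean_lfc = res.table["log2FoldChange"].iloc[:nresp].mean()
        assert 0.8 <= mean_lfc <= 1.2

    def test_batch_effect_absorbed_by_covariate(self, rng):
        """A gene-wise multiplicative batch factor on half the genes leaves
        the condition log2FC unbiased once the batch term is in the design."""
        G, n, alpha = 800, 3, 0.01
        mu = rng.lognormal(5.5, 0.5, G)
        batch_fac = np.ones(G)
        batch_fac[: G // 2] = rng.lognormal(0.5, 0.2, G // 2)
        fc = np.ones(G)
        fc[:100] = 2.0
        # batch 1: control+treated; batch 2: control+treated, batch factor applied
        blocks, batches, cond = [], [], []
        for b, bf in [(1, np.ones(G)), (2, batch_fac)]:
            blocks.append(nb_counts(rng, mu * bf, alpha, n))
            blocks.append(nb_counts(rng, mu * bf * fc, alpha, n))
            batches += [f"b{b}"] * (2 * n)
            cond += [0] * n + [1] * n
        cm = make_cm(np.hstack(blocks))
        batch = pd.Series(batches, index=cm.sample_ids)
        treated = [s for s, c in zip(cm.sample_ids, cond) if c == 1]
        control = [s for s, c in zip(cm.sample_ids, cond) if c == 0]
        res = DEModel(cm, None, treated, control, batch=batch).fit()
        bias = res.table["log2FoldChange"].iloc[:100].mean() - 1.0
        assert abs(bias) < 0.1

    def test_swapping_contrast_negates_lfc_and_stat(self, rng):
        cm, n = self._null_cm(rng, G=100)
        trt = [f"s{j}" for j in range(n, 2 * n)]
        ctl = [f"s{j}" for j in range(n)]
        disp = pd.Series(0.05, index=cm.probe_ids)
        fwd = DEModel(cm, None, trt, ctl, dispersions=disp).fit()
        rev = DEModel(cm, None, ctl, trt, dispersions=disp).fit()
        assert np.allclose(
            fwd.table["log2FoldChange"], -rev.table["log2FoldChange"], atol=1e-6
        )
        assert np.allclose(fwd.table["pvalue"], rev.table["pvalue"], atol=1e-8)

    def test_sample_scaling_leaves_lfc_invariant_noise_free(self, rng):
        """On noise-free data, scaling one sample's counts by k changes only
        that sample's size factor (by k up to renormalization)."""
        q = rng.integers(20, 200, size=60)
        lib = np.array([1, 2, 1, 1, 2, 4])
        fc = 3
        fc_vec = np.ones(60, dtype=int)
        fc_vec[:10] = fc  # minority responds, so normalization is untouched
        K = np.column_stack(
            [q * lib[j] * (fc_vec if j >= 3 else 1) for j in range(6)]
        )
        cm = make_cm(K)
        disp = pd.Series(0.05, index=cm.probe_ids)
        trt = ["s3", "s4", "s5"]
        ctl = ["s0", "s1", "s2"]
        base = DEModel(cm, None, trt, ctl, dispersions=disp).fit()
        scaled = cm.counts.copy()
        scaled["s0"] = scaled["s0"] * 4
        res = DEModel(CountMatrix(scaled), None, trt, ctl, dispersions=disp).fit()
        # renormalization spreads the x4 over all factors; the ratio of
        # ratios isolates the scaled sample's change
        rel = (res.size_factors["s0"] / res.size_factors["s1"]) / (
            base.size_factors["s0"] / base.size_factors["s1"]
        )
        assert rel == pytest.approx(4.0, rel=1e-9)
        assert np.allclose(base.table["log2FoldChange"].iloc[:10], np.log2(fc), atol=1e-6)
        assert np.allclose(
            base.table["log2FoldChange"],
            res.table["log2FoldChange"],
            atol=1e-6,
        )

    def test_confounded_design_rejected(self, rng):
        cm, n = self._null_cm(rng, G=20)
        trt = [f"s{j}" for j in range(n, 2 * n)]
        ctl = [f"s{j}" for j in range(n)]
        batch = pd.Series(
            ["b1"] * n + ["b2"] * n, index=cm.sample_ids
        )  # batch == condition
        with pytest.raises(DesignError, match="confounded"):
            DEModel(cm, None, trt, ctl, batch=batch).fit()

    def test_all_zero_genes_flagged_not_tested(self, rng):
        K = nb_counts(rng, np.full(10, 100.0), 0.05, 6)
        K[3] = 0
        cm = make_cm(K)
        res = DEModel(
            cm, None, ["s3", "s4", "s5"], ["s0", "s1", "s2"]
        ).fit()
        row = res.table.iloc[3]
        assert np.isnan(row["pvalue"]) and not row["converged"]


class TestBHAdjust:
    def test_printed_stepup_example(self):
        padj = bh_adjust(pd.Series([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(padj, 0.04)

    def test_single_p_unchanged(self):
        assert bh_adjust(pd.Series([0.03])).iloc[0] == pytest.approx(0.03)

    def test_all_ones_stay_one(self):
        assert (bh_adjust(pd.Series([1.0, 1.0, 1.0])) == 1.0).all()

    def test_padj_dominates_p(self, rng):
        p = pd.Series(rng.uniform(0, 1, 200))
        assert (bh_adjust(p) >= p - 1e-12).all()

    def test_nan_propagates(self):
        out = bh_adjust(pd.Series([0.01, np.nan, 0.5]))
        assert np.isnan(out.iloc[1]) and out.notna().sum() == 2

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(pd.Series([1.5]))


class TestSignificanceFilter:
    @pytest.mark.parametrize(
        "basemean,padj,lfc,kept",
        [
            (12.0, 0.04, 0.60, True),
            (12.0, 0.04, 0.585, False),  # strict >
            (9.0, 0.001, 3.0, False),  # baseMean rule
            (12.0, 0.05, 1.0, False),  # strict <
            (12.0, 0.04, -0.60, True),  # absolute value
        ],
    )
    def test_strict_thresholds(self, basemean, padj, lfc, kept):
        t = pd.DataFrame(
            {"baseMean": [basemean], "padj": [padj], "log2FoldChange": [lfc]},
            index=["g"],
        )
        assert (len(significance_filter(t)) == 1) is kept


class TestAgainstDESeq2Reference:
    def test_log2fc_agrees_with_independent_implementation(self, rng):
        """Cross-check the genewise NB fold-change estimates against an
        independent DESeq2 implementation on a clean fixture."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        G, n, alpha = 200, 4, 0.02
        mu = rng.lognormal(5.5, 0.6, G)
        fc = 2.0 ** rng.uniform(-2, 2, G)
        Kc = nb_counts(rng, mu, alpha, n)
        Kt = nb_counts(rng, fc * mu, alpha, n)
        cm = make_cm(np.hstack([Kc, Kt]))
        trt = [f"s{j}" for j in range(n, 2 * n)]
        ctl = [f"s{j}" for j in range(n)]
        ours = DEModel(cm, None, trt, ctl).fit()

        counts = cm.counts.T
        meta = pd.DataFrame(
            {"condition": ["A"] * n + ["B"] * n}, index=counts.index
        )
        dds = DeseqDataSet(
            counts=counts, metadata=meta, design="~condition", quiet=True
        )
        dds.deseq2()
        ds = DeseqStats(dds, contrast=["condition", "B", "A"], quiet=True)
        ds.summary()
        ref = ds.results_df["log2FoldChange"]
        both = pd.DataFrame({"ours": ours.table["log2FoldChange"], "ref": ref}).dropna()
        assert both["ours"].corr(both["ref"]) > 0.99
        assert (both["ours"] - both["ref"]).abs().median() < 0.05
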