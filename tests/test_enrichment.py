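import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from toxsig.enrichment import (
    activation_zscore,
    ora_zscore,
    overlap_pvalue,
    permutation_pvalue,
    read_gmt,
    run_ora,
    run_upstream,
)
from toxsig.errors import FormatError


class TestReadGmt:
    def test_two_set_toy_file(self, tmp_path):
        p = tmp_path / "db.gmt"
        p.write_text("setA\tdesc\tg1\tg2\nsetB\tdesc\tg3\n")
        db = read_gmt(p)
        assert set(db.sets) == {"setA", "setB"}
        assert db.sets["setA"] == ["g1", "g2"]

    def test_duplicate_member_deduplicated(self, tmp_path):
        p = tmp_path / "db.gmt"
        p.write_text("setA\tdesc\tg1\tg1\tg2\n")
        assert read_gmt(p).sets["setA"] == ["g1", "g2"]

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "db.gmt"
        p.write_text("setA\tdesc\tg1\njustonecolumn\n")
        with pytest.raises(FormatError, match="line 2"):
            read_gmt(p)

    def test_empty_set_dropped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "db.gmt"
        p.write_text("setA\tdesc\nsetB\tdesc\tg1\n")
        with caplog.at_level("WARNING"):
            db = read_gmt(p)
        assert set(db.sets) == {"setB"}


def hypergeom_moments(N, R, n):
    """Mean and variance of the selected-in-set count by explicit
    enumeration of the hypergeometric pmf (independent of scipy)."""
    total = math.comb(N, n)
    mean = 0.0
    second = 0.0
    for r in range(0, min(n, R) + 1):
        pm = math.comb(R, r) * math.comb(N - R, n - r) / total
        mean += r * pm
        second += r * r * pm
    return mean, second - mean**2


class TestOraZscore:
    def test_zero_at_hypergeometric_mean(self):
        assert ora_zscore(100, 20, 10, 2) == 0.0

    def test_printed_formula_value(self):
        assert ora_zscore(2907, 500, 40, 15) == pytest.approx(3.43, abs=0.01)

    def test_matches_enumerated_moments_small_universes(self):
        for N in (5, 9, 12):
            for R in range(0, N + 1):
                for n in range(1, N):
                    mean, var = hypergeom_moments(N, R, n)
                    if var == 0:
                        continue
                    for r in range(0, min(n, R) + 1):
                        z = ora_zscore(N, R, n, r)
                        assert z == pytest.approx((r - mean) / math.sqrt(var), rel=1e-12)

    def test_degenerate_universe_rejected(self):
        with pytest.raises(ZeroDivisionError):
            ora_zscore(10, 5, 10, 5)

    @pytest.mark.parametrize("bad", [(10, 11, 3, 1), (10, 5, 3, 4), (10, 5, 0, 0)])
    def test_invalid_arguments_rejected(self, bad):
        with pytest.raises(ValueError):
            ora_zscore(*bad)


class TestPermutationPvalue:
    def test_matches_exact_tail_on_tiny_universe(self):
        """Label permutation reduces to the hypergeometric null: compare
        with the exhaustively enumerated tail probability."""
        N, n, R = 8, 3, 3
        selected = np.zeros(N, dtype=bool)
        selected[:R] = True
        set_mask = np.zeros(N, dtype=bool)
        set_mask[:n] = True  # observed r = 3, the maximum
        # exact: P(r_perm = 3) over C(8,3) label placements
        exact = sum(
            1
            for combo in itertools.combinations(range(N), R)
            if sum(i < n for i in combo) == 3
        ) / math.comb(N, R)
        p = permutation_pvalue(selected, set_mask, n_perm=50_000, seed=4)
        se = math.sqrt(exact * (1 - exact) / 50_000)
        assert abs(p - exact) < 3 * se + 1e-4

    def test_whole_universe_minus_one_not_enrichable(self):
        selected = np.array([True] * 6 + [False] * 2)
        set_mask = np.array([True] * 7 + [False])
        p = permutation_pvalue(selected, set_mask, n_perm=500, seed=0)
        assert p > 0.2

    def test_fixed_seed_reproducible(self):
        selected = np.array([True] * 5 + [False] * 15)
        set_mask = np.array([True] * 4 + [False] * 16)
        a = permutation_pvalue(selected, set_mask, n_perm=300, seed=7)
        b = permutation_pvalue(selected, set_mask, n_perm=300, seed=7)
        assert a == b

    def test_nperm_must_be_positive(self):
        with pytest.raises(ValueError):
            permutation_pvalue(np.array([True, False]), np.array([True, False]), n_perm=0)


class TestRunOra:
    def test_planted_set_flagged_decoys_not(self, rng):
        universe = [f"g{i}" for i in range(400)]
        selected = universe[:40]
        sets = {"planted": universe[:30]}
        for i in range(50):
            sets[f"decoy{i}"] = list(rng.choice(universe, 30, replace=False))
        from toxsig.enrichment import GeneSetDB

        res = run_ora(selected, universe, GeneSetDB(sets), n_perm=400, seed=1)
        res = res.set_index("set")
        assert res.loc["planted", "significant"]
        decoy_flags = res.drop("planted")["significant"]
        assert decoy_flags.mean() <= 0.05

    def test_empty_selection_yields_no_hits(self):
        universe = [f"g{i}" for i in range(50)]
        from toxsig.enrichment import GeneSetDB

        db = GeneSetDB({"s1": universe[:10], "s2": universe[10:20]})
        res = run_ora([], universe, db, n_perm=100, seed=0)
        assert (res["Z"] <= 0).all()
        assert not res["significant"].any()

    def test_unmeasured_set_skipped(self, caplog):
        universe = [f"g{i}" for i in range(20)]
        from toxsig.enrichment import GeneSetDB

        db = GeneSetDB({"ghost": ["x1", "x2"], "real": universe[:5]})
        with caplog.at_level("WARNING"):
            res = run_ora(universe[:3], universe, db, n_perm=50, seed=0)
        assert list(res["set"]) == ["real"]


class TestActivationZscore:
    def _edges(self, signs, weights):
        return pd.DataFrame(
            {
                "regulator": ["R"] * len(signs),
                "target": [f"t{i}" for i in range(len(signs))],
                "sign": signs,
                "weight": weights,
            }
        )

    def test_consistent_unit_weights_sqrt_k(self):
        edges = self._edges([1] * 4, [1.0] * 4)
        obs = pd.Series({f"t{i}": 1 for i in range(4)})
        res = activation_zscore(edges, obs)
        assert res.activation_z == pytest.approx(2.0)
        assert res.predicted_state == "activated"

    def test_balanced_signs_cancel(self):
        edges = self._edges([1, 1, -1, -1], [1.0] * 4)
        obs = pd.Series({f"t{i}": 1 for i in range(4)})
        res = activation_zscore(edges, obs)
        assert res.activation_z == pytest.approx(0.0)
        assert res.predicted_state == "none"

    def test_weighted_example(self):
        # weights (2,1,1), contributions (+,+,-): (2+1-1)/sqrt(6)
        edges = self._edges([1, 1, 1], [2.0, 1.0, 1.0])
        obs = pd.Series({"t0": 1, "t1": 1, "t2": -1})
        res = activation_zscore(edges, obs)
        assert res.activation_z == pytest.approx(2 / math.sqrt(6))

    def test_unobserved_targets_excluded(self):
        edges = self._edges([1] * 5, [1.0] * 5)
        obs = pd.Series({"t0": 1, "t1": 1})  # only two targets measured DE
        res = activation_zscore(edges, obs)
        assert res.n_overlap == 2
        assert res.activation_z == pytest.approx(math.sqrt(2))

    def test_no_overlap_flagged_none(self):
        edges = self._edges([1], [1.0])
        res = activation_zscore(edges, pd.Series({"other": 1}))
        assert res.predicted_state == "none" and np.isnan(res.activation_z)

    @given(
        c=st.floats(min_value=0.1, max_value=50.0),
        k=st.integers(min_value=1, max_value=8),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_weight_scale_invariance_and_sign_antisymmetry(self, c, k):
        r = np.random.default_rng(k)
        signs = r.choice([-1, 1], k)
        weights = r.uniform(0.5, 2.0, k)
        obs = pd.Series({f"t{i}": int(s) for i, s in enumerate(r.choice([-1, 1], k))})
        z1 = activation_zscore(self._edges(signs, weights), obs).activation_z
        z2 = activation_zscore(self._edges(signs, c * weights), obs).activation_z
        z3 = activation_zscore(self._edges(signs, weights), -obs).activation_z
        assert z2 == pytest.approx(z1, rel=1e-9)
        assert z3 == pytest.approx(-z1, rel=1e-9)


class TestOverlapPvalue:
    def test_matches_enumerated_fisher_tail(self):
        # 2x2 table (8,2; 2,88): right tail of the hypergeometric
        universe = [f"g{i}" for i in range(100)]
        targets = universe[:10]
        selected = universe[:8] + universe[10:12]
        p = overlap_pvalue(targets, selected, universe)
        N, K, n = 100, 10, 10  # universe, targets, selected
        exact = sum(
            math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)
            for k in range(8, min(K, n) + 1)
        )
        assert p == pytest.approx(exact, rel=1e-9)

    def test_expected_overlap_not_significant(self, rng):
        universe = [f"g{i}" for i in range(200)]
        targets = universe[:20]
        selected = universe[18:38]  # overlap 2 = expectation
        assert overlap_pvalue(targets, selected, universe) > 0.3

    def test_empty_targets_give_one(self):
        assert overlap_pvalue([], ["a"], ["a", "b"]) == 1.0


class TestRunUpstream:
    def test_state_gated_on_overlap_significance(self):
        net = pd.DataFrame(
            {
                "regulator": ["R1"] * 6 + ["R2"] * 6,
                "target": [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)],
                "sign": [1] * 12,
                "weight": [1.0] * 12,
            }
        )
        universe = (
            [f"a{i}" for i in range(6)]
            + [f"b{i}" for i in range(6)]
            + [f"x{i}" for i in range(200)]
        )
        # R1 targets all DE and consistent; R2 targets barely overlap
        observed = pd.Series({f"a{i}": 1 for i in range(6)} | {"b0": 1})
        res = run_upstream(net, observed, universe).set_index("regulator")
        assert res.loc["R1", "predicted_state"] == "activated"
        assert res.loc["R2", "predicted_state"] == "none"
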