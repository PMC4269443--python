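"""Rank statistics: identities, oracles, calibration of the implementations."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sps

import bilescreen as bs
from bilescreen.stats import (
    INCONSISTENT_RANK_SUMMARIES,
    PUBLISHED_RANK_SUMMARIES,
    printing_tolerance,
    reconstruct_constellation,
)


class TestPooledMidRanks:
    def test_no_ties_example(self):
        rs = bs.pooled_mid_ranks([1, 2, 3, 4], ["a", "a", "b", "b"])
        assert rs.mean_rank("a") == 1.5 and rs.mean_rank("b") == 3.5

    def test_full_ties_example(self):
        rs = bs.pooled_mid_ranks([5, 5, 5, 5], ["a", "a", "b", "b"])
        assert rs.mean_rank("a") == rs.mean_rank("b") == 2.5

    @settings(derandomize=True, max_examples=50)
    @given(
        hst.lists(hst.integers(0, 5), min_size=2, max_size=30),
        hst.data(),
    )
    def test_rank_sum_identity_holds_exactly(self, values, data):
        labels = data.draw(
            hst.lists(
                hst.sampled_from(["a", "b", "c"]),
                min_size=len(values), max_size=len(values),
            )
        )
        if len(set(labels)) < 2:
            labels[0] = "a"
            labels[-1] = "b"
        rs = bs.pooled_mid_ranks(values, labels)
        n = rs.n_total
        total = sum(gn * mr for _, gn, mr in rs.groups)
        assert total == pytest.approx(n * (n + 1) / 2)


class TestReconstruction:
    def test_ibd_cohort_control_mean_rank(self):
        """(114, 21, 25) with CD = 110.48 and UC = 72.00 pins control at 76.84."""
        mr = bs.reconstruct_missing_mean_rank(
            [114, 21, 25], [None, 110.48, 72.00]
        )
        assert round(mr, 2) == 76.84

    def test_t2dm_cohort_diabetic_mean_rank(self):
        """(100, 99) with control = 109.43 pins the diabetic group at 90.47."""
        mr = bs.reconstruct_missing_mean_rank([100, 99], [109.43, None])
        assert round(mr, 2) == 90.47

    def test_symmetric_groups(self):
        n = 10
        mid = (2 * n + 1) / 2
        assert bs.reconstruct_missing_mean_rank([n, n], [mid, None]) == mid

    def test_requires_exactly_one_unknown(self):
        with pytest.raises(ValueError):
            bs.reconstruct_missing_mean_rank([5, 5], [3.0, 8.0])
        with pytest.raises(ValueError):
            bs.reconstruct_missing_mean_rank([5, 5], [None, None])

    def test_published_constellations_satisfy_identity(self):
        for name, groups in PUBLISHED_RANK_SUMMARIES.items():
            assert abs(bs.rank_sum_residual(groups)) <= printing_tolerance(groups), name

    def test_inconsistent_constellations_are_flagged(self):
        for name, groups in INCONSISTENT_RANK_SUMMARIES.items():
            assert abs(bs.rank_sum_residual(groups)) > printing_tolerance(groups), name

    def test_designated_heldout_value_reconstructs_to_two_decimals(self):
        from bilescreen.stats import RECONSTRUCTION_HOLDOUT

        for name, groups in PUBLISHED_RANK_SUMMARIES.items():
            label = RECONSTRUCTION_HOLDOUT[name]
            printed = next(mr for lab, _, mr in groups if lab == label)
            rec = reconstruct_constellation(groups, label)
            assert rec == pytest.approx(printed, abs=0.0075), (name, label)

    def test_every_heldout_value_reconstructs_within_propagated_precision(self):
        from bilescreen.stats import reconstruction_tolerance

        for name, groups in PUBLISHED_RANK_SUMMARIES.items():
            for label, _, printed in groups:
                rec = reconstruct_constellation(groups, label)
                tol = reconstruction_tolerance(groups, label)
                assert rec == pytest.approx(printed, abs=tol), (name, label)


class TestKruskalWallis:
    def test_matches_scipy_with_ties(self, rng):
        for _ in range(10):
            v = rng.integers(0, 8, size=30).astype(float)
            l = rng.choice(["a", "b", "c"], size=30)
            if len(set(l)) < 3 or len(set(v)) < 2:
                continue
            mine = bs.kruskal_wallis(v, l)
            h, p = sps.kruskal(v[l == "a"], v[l == "b"], v[l == "c"])
            assert mine.statistic == pytest.approx(h)
            assert mine.p_value == pytest.approx(p)

    def test_small_example_against_rank_oracle(self):
        # groups {1,2},{3,4},{5,6}: H computable by hand from the ranks
        v = [1, 2, 3, 4, 5, 6]
        l = ["a", "a", "b", "b", "c", "c"]
        mine = bs.kruskal_wallis(v, l)
        h, _ = sps.kruskal([1, 2], [3, 4], [5, 6])
        assert mine.statistic == pytest.approx(h)
        # exhaustive permutation distribution of H for the exact p
        obs = mine.statistic
        count = 0
        total = 0
        for perm in itertools.permutations(range(6)):
            pv = [v[i] for i in perm]
            ph = bs.kruskal_wallis(pv, l, posthoc=False).statistic
            count += ph >= obs - 1e-12
            total += 1
        exact_p = count / total
        assert 0 < exact_p < 0.2  # complete separation is rare under the null

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(99)
        n_rej = 0
        sims = 400
        for _ in range(sims):
            v = rng.normal(size=60)
            l = np.repeat(["a", "b", "c"], 20)
            n_rej += bs.kruskal_wallis(v, l, posthoc=False).p_value < 0.05
        assert 0.02 <= n_rej / sims <= 0.08

    def test_all_equal_reports_no_variance(self):
        res = bs.kruskal_wallis([3.0] * 9, ["a", "b", "c"] * 3)
        assert res.no_variance and res.p_value == 1.0

    def test_dunn_pairwise_capped_at_one(self, rng):
        v = rng.normal(size=30)
        l = np.repeat(["a", "b", "c"], 10)
        res = bs.kruskal_wallis(v, l)
        assert len(res.pairwise) == 3
        assert all(0 <= p <= 1 for p in res.pairwise.values())

    def test_dunn_detects_shifted_group(self):
        rng = np.random.default_rng(5)
        v = np.concatenate([rng.normal(0, 1, 30), rng.normal(4, 1, 30), rng.normal(0, 1, 30)])
        l = np.repeat(["a", "b", "c"], 30)
        res = bs.kruskal_wallis(v, l)
        assert res.pairwise[("a", "b")] < 0.01
        assert res.pairwise[("a", "c")] == 1.0  # Bonferroni cap on a null pair


class TestMannWhitney:
    def test_complete_separation_example(self):
        res = bs.mann_whitney_u([1, 2, 3, 4], ["a", "a", "b", "b"])
        assert res.u_statistics == (0.0, 4.0)  # group a never wins

    @settings(derandomize=True, max_examples=50)
    @given(hst.lists(hst.floats(0, 100), min_size=4, max_size=40))
    def test_u_identity(self, values):
        labels = ["a" if i % 2 else "b" for i in range(len(values))]
        res = bs.mann_whitney_u(values, labels)
        n1 = labels.count("a")
        n2 = labels.count("b")
        u1, u2 = res.u_statistics
        assert u1 + u2 == pytest.approx(n1 * n2)

    def test_matches_scipy(self, rng):
        for _ in range(10):
            v = rng.integers(0, 10, size=24).astype(float)
            l = np.repeat(["a", "b"], 12)
            if len(set(v)) < 2:
                continue
            mine = bs.mann_whitney_u(v, l)
            u, p = sps.mannwhitneyu(v[:12], v[12:], method="asymptotic")
            assert mine.statistic == pytest.approx(u)
            assert mine.p_value == pytest.approx(p)

    def test_p_close_to_exact_enumeration(self):
        """n1 = n2 = 8 distinct values: the normal approximation must be
        within 0.02 of the exact permutation p-value."""
        rng = np.random.default_rng(23)
        v = rng.permutation(16).astype(float)
        l = np.repeat(["a", "b"], 8)
        mine = bs.mann_whitney_u(v, l)
        # exact: enumerate all C(16,8) splits of the observed values
        obs_u1 = mine.u_statistics[0]
        n1 = n2 = 8
        mu = n1 * n2 / 2
        count = total = 0
        from scipy.stats import rankdata

        r = rankdata(v)
        for idx in itertools.combinations(range(16), 8):
            r1 = sum(r[i] for i in idx)
            u1 = n1 * n2 + n1 * (n1 + 1) / 2 - r1
            count += abs(u1 - mu) >= abs(obs_u1 - mu) - 1e-12
            total += 1
        assert mine.p_value == pytest.approx(count / total, abs=0.02)

    def test_all_equal_reports_no_variance(self):
        res = bs.mann_whitney_u([2.0] * 8, ["a", "b"] * 4)
        assert res.no_variance and res.p_value == 1.0

    def test_power_on_twofold_cluster_effect(self, community_small):
        """A 2× group effect on cluster-1 genomes at n = 100/99 with the
        default Dirichlet noise must be detected in >= 80% of replicates
        (checked on the recorded ground-truth abundances)."""
        spec = bs.CohortSpec(
            groups=[("control", 100), ("disease", 99)],
            base_weights=bs.BASE_WEIGHTS,
            effects=bs.disease_effects(0.5),
            compensator="g_background",
            read_count=100,
            error_rate=0.0,
            seed=0,
        )
        rng = np.random.default_rng(31)
        c1 = set(bs.community.CLUSTER1_GENOMES)
        ids = [g.genome_id for g in community_small.genomes]
        sel = np.array([gid in c1 for gid in ids])
        rejections = 0
        reps = 200
        for _ in range(reps):
            profiles = bs.synthetic.sample_profiles(spec, community_small.genomes, rng)
            values = [sum(w for gid, w in p.weights.items() if gid in c1)
                      for _, _, p in profiles]
            labels = [grp for _, grp, _ in profiles]
            res = bs.mann_whitney_u(values, labels)
            rejections += res.p_value < 0.05
        assert rejections / reps >= 0.8


class TestSpearman:
    def test_monotone_pair_gives_rho_one(self):
        import pandas as pd

        cols = pd.DataFrame({"x": [1.0, 2, 3, 4, 5, 6]})
        out = bs.spearman_heatmap(cols, [0, 0, 0, 1, 1, 1], sum_row=False)
        # x is monotone in the indicator's order but rho is vs the indicator
        rho = out.loc[out["stratum"] == "x", "rho"].iloc[0]
        assert rho == pytest.approx(sps.spearmanr([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1]).statistic)

    def test_rho_equals_pearson_on_ranks(self, rng):
        import pandas as pd
        from scipy.stats import rankdata

        x = rng.normal(size=20)
        ind = rng.integers(0, 2, size=20)
        out = bs.spearman_heatmap(pd.DataFrame({"x": x}), ind, sum_row=False)
        rho = out["rho"].iloc[0]
        pear = np.corrcoef(rankdata(x), rankdata(ind))[0, 1]
        assert rho == pytest.approx(pear)

    def test_zero_variance_column_flagged_na(self):
        import pandas as pd

        out = bs.spearman_heatmap(
            pd.DataFrame({"x": [1.0] * 6}), [0, 1] * 3, sum_row=False
        )
        assert out["flag"].iloc[0] == "NA" and np.isnan(out["rho"].iloc[0])

    def test_sum_row_present(self, rng):
        import pandas as pd

        cols = pd.DataFrame({"a": rng.normal(size=10), "b": rng.normal(size=10)})
        out = bs.spearman_heatmap(cols, rng.integers(0, 2, size=10))
        assert "Sum" in set(out["stratum"])


class TestFormatP:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.0004, "<0.001"), (0.007, "0.007"), (1.0, "1.000"), (0.0501, "0.050")],
    )
    def test_rendering(self, p, expected):
        assert bs.format_p(p) == expected
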