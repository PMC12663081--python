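import numpy as np
import pytest

from dynhub.association import (
    identify_dcmn,
    linked_mode,
    linked_mode_association,
    partial_spearman,
    permutation_test,
    spearman,
)
from dynhub.errors import (
    DegenerateStatisticError,
    ParameterError,
    StructureError,
)
from dynhub.modes import ModeModel
from dynhub.topology import BinaryGraphSeries


class TestSpearman:
    def test_perfect_inverse(self):
        assert spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_perfect_direct(self):
        assert spearman([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]) == pytest.approx(1.0)

    def test_constant_input_degenerate(self):
        with pytest.raises(DegenerateStatisticError):
            spearman([1, 2, 3, 4, 5], [2, 2, 2, 2, 2])

    def test_matches_scipy_with_ties(self, rng):
        from scipy.stats import spearmanr

        x = rng.integers(0, 5, 30).astype(float)
        y = rng.integers(0, 5, 30).astype(float)
        assert spearman(x, y) == pytest.approx(
            spearmanr(x, y).statistic, abs=1e-12
        )

    def test_short_input_rejected(self):
        with pytest.raises(ParameterError):
            spearman([1, 2], [2, 1])


class TestPermutationTest:
    def test_strong_negative_association_detected(self, rng):
        uls = np.tile([0, 1, 2, 3, 4], 4).astype(float)
        metric = -uls + 0.01 * rng.standard_normal(20)
        res = permutation_test(metric, uls, n_perm=1000, seed=0)
        assert res.significant and res.p_perm <= 0.01 and res.rho < -0.9

    def test_same_seed_identical_null(self):
        metric = np.arange(20.0)
        uls = np.tile([0, 1, 2, 3, 4], 4)
        a = permutation_test(metric, uls, seed=3)
        b = permutation_test(metric, uls, seed=3)
        assert (a.null_q99, a.p_perm, a.significant) == (
            b.null_q99,
            b.p_perm,
            b.significant,
        )

    def test_degenerate_metric_returns_flagged_result(self):
        res = permutation_test(np.ones(20), np.tile([0, 1, 2, 3, 4], 4), seed=0)
        assert res.degenerate and not res.significant

    def test_p_value_floor(self, rng):
        uls = np.tile([0, 1, 2, 3, 4], 4).astype(float)
        res = permutation_test(-uls, uls, n_perm=500, seed=0)
        assert res.p_perm >= 1 / 501

    def test_one_sided_negative_mode(self, rng):
        uls = np.tile([0, 1, 2, 3, 4], 4).astype(float)
        metric = -uls + 0.01 * rng.standard_normal(20)
        res = permutation_test(metric, uls, seed=0, alternative="less")
        assert res.significant
        pos = permutation_test(-metric, uls, seed=0, alternative="less")
        assert not pos.significant  # positive association is ignored

    def test_null_rejection_rate_near_nominal(self, rng):
        """The |rho| > q99(signed null) rule is a ~2% two-sided level;
        over 200 independent null draws the rejection count should be small
        (binomially consistent with 0.02)."""
        uls = np.tile([0, 1, 2, 3, 4], 4)
        hits = sum(
            permutation_test(
                rng.standard_normal(20), uls, n_perm=500, seed=k
            ).significant
            for k in range(200)
        )
        assert hits <= 12  # P(X > 12 | n=200, p=0.02) < 1e-4


class TestIdentifyDcmn:
    def _occupancy(self, rng, signal_node=3, n_nodes=8):
        uls = np.tile([0, 1, 2, 3, 4], 4).astype(float)
        occ = rng.standard_normal((20, n_nodes))
        occ[:, signal_node] = -uls + 0.05 * rng.standard_normal(20)
        return occ, uls

    def test_planted_node_found(self, rng):
        occ, uls = self._occupancy(rng)
        dcmn, results = identify_dcmn(occ, uls, seed=0)
        assert dcmn == 3
        assert results[3].rho < 0
        assert len(results) == 8

    def test_no_signal_gives_none(self, rng):
        occ = rng.standard_normal((20, 6))
        uls = np.tile([0, 1, 2, 3, 4], 4)
        # verify explicitly: with no significant node the DCMN is undefined
        dcmn, results = identify_dcmn(occ, uls, seed=1)
        if any(r.significant for r in results):
            pytest.skip("rare null fluctuation reached significance")
        assert dcmn is None

    def test_largest_abs_rho_wins(self, rng):
        uls = np.tile([0, 1, 2, 3, 4], 4).astype(float)
        occ = rng.standard_normal((20, 4))
        occ[:, 1] = uls + 1.0 * rng.standard_normal(20)  # weaker, positive
        occ[:, 2] = -uls + 0.01 * rng.standard_normal(20)  # stronger, negative
        dcmn, results = identify_dcmn(occ, uls, seed=0)
        assert dcmn == 2
        assert results[1].significant  # both appear in the table

    def test_node_order_invariance(self, rng):
        occ, uls = self._occupancy(rng)
        perm = rng.permutation(occ.shape[1])
        dcmn_a, _ = identify_dcmn(occ, uls, seed=5)
        dcmn_b, _ = identify_dcmn(occ[:, perm], uls, seed=5)
        assert perm[dcmn_b] == dcmn_a


def _graph_series(adj_list):
    return BinaryGraphSeries("s", np.stack(adj_list), density=0.2)


class TestLinkedMode:
    def _setup(self):
        # 3 nodes, 4 windows; DCMN = node 0
        def adj(edges):
            a = np.zeros((3, 3), dtype=np.uint8)
            for i, j in edges:
                a[i, j] = a[j, i] = 1
            return a

        graphs = [
            _graph_series(
                [adj([(0, 1)]), adj([(1, 2)]), adj([(0, 2)]), adj([(0, 1), (0, 2)])]
            )
        ]
        model = ModeModel(
            node=0,
            k=2,
            centroids=np.array([1.0, 2.5]),
            labels=[np.array([0, 1, 0, 0])],  # HCM windows: 0, 2, 3
            hcm_id=0,
            mpfc_by_k={2: 1.0},
        )
        return graphs, model

    def test_counts(self):
        graphs, model = self._setup()
        lm = linked_mode(graphs, model, dcmn=0)
        assert list(lm.columns) == [1, 2]  # DCMN column excluded
        assert lm.loc["s", 1] == 2  # windows 0 and 3
        assert lm.loc["s", 2] == 2  # windows 2 and 3

    def test_bounded_by_hcm_count(self):
        graphs, model = self._setup()
        lm = linked_mode(graphs, model, dcmn=0)
        hcm_count = int((model.labels[0] == 0).sum())
        assert (lm.to_numpy() <= hcm_count).all()

    def test_no_hcm_windows_gives_zero(self):
        graphs, model = self._setup()
        model.labels = [np.array([1, 1, 1, 1])]
        lm = linked_mode(graphs, model, dcmn=0)
        assert (lm.to_numpy() == 0).all()

    def test_length_mismatch_rejected(self):
        graphs, model = self._setup()
        model.labels = [np.array([0, 1])]
        with pytest.raises(StructureError, match="s"):
            linked_mode(graphs, model, dcmn=0)

    def test_association_excludes_dcmn(self, rng):
        import pandas as pd

        lm = pd.DataFrame(
            rng.integers(0, 30, (20, 3)), columns=[1, 2, 4]
        )
        results = linked_mode_association(
            lm, np.tile([0, 1, 2, 3, 4], 4), n_perm=200, seed=0
        )
        assert [r.node for r in results] == [1, 2, 4]


class TestPartialSpearman:
    def test_independent_covariate_leaves_rho(self, rng):
        n = 200
        x = rng.standard_normal(n)
        y = x + rng.standard_normal(n)
        c = rng.standard_normal(n)
        assert partial_spearman(x, y, c) == pytest.approx(spearman(x, y), abs=0.1)

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        n = 40
        df = pd.DataFrame(
            {
                "x": rng.standard_normal(n),
                "y": rng.standard_normal(n),
                "c": rng.standard_normal(n),
            }
        )
        ours = partial_spearman(df["x"], df["y"], df["c"])
        ref = pg.partial_corr(df, x="x", y="y", covar="c", method="spearman")
        assert ours == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)

    def test_metric_equal_covariate_degenerate(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        with pytest.raises(DegenerateStatisticError):
            partial_spearman(x, y, x)

    def test_constant_covariate_falls_back(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        assert partial_spearman(x, y, np.ones(30)) == pytest.approx(spearman(x, y))

    def test_removes_confounded_association(self, rng):
        n = 300
        c = rng.standard_normal(n)
        x = c + 0.3 * rng.standard_normal(n)
        y = c + 0.3 * rng.standard_normal(n)
        assert abs(spearman(x, y)) > 0.7
        assert abs(partial_spearman(x, y, c)) < 0.25
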