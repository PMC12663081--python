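import numpy as np
import pytest
from scipy.stats import spearmanr

from dynhub.errors import ParameterError
from dynhub.synthetic import (
    SyntheticCohortSpec,
    assign_uls,
    make_state_covariances,
    simulate_cohort,
    simulate_subject,
    state_structure,
    write_cohort,
)
from dynhub.topology import proportional_threshold

from ._oracles import brute_betweenness


class TestStateCovariances:
    def test_three_node_hub_profile(self):
        hub, _ = make_state_covariances(3, 0, seed=0)
        assert abs(hub[0, 1]) >= 0.6 and abs(hub[0, 2]) >= 0.6
        assert abs(hub[1, 2]) <= 0.2

    @pytest.mark.parametrize("n,h", [(3, 0), (12, 3), (20, 5), (20, 19)])
    def test_both_matrices_positive_definite(self, n, h):
        for mat in make_state_covariances(n, h, seed=1):
            assert np.linalg.eigvalsh(mat).min() > 0
            np.testing.assert_allclose(np.diag(mat), 1.0)
            np.testing.assert_allclose(mat, mat.T)

    def test_hub_most_central_after_thresholding(self):
        """On the noiseless hub-state matrix thresholded at 20% density the
        hub node attains the top betweenness, per exhaustive path counting
        on the satellite component (brute-force oracle)."""
        hub_idx = 5
        hub, _ = make_state_covariances(20, hub_idx, seed=0)
        adj = proportional_threshold(hub, 0.20)
        # restrict the brute-force enumeration to the hub's component
        roles = state_structure(20, hub_idx)
        comp = sorted({hub_idx, *roles.satellites_a, *roles.satellites_b})
        sub = adj[np.ix_(comp, comp)]
        bc = brute_betweenness(sub)
        assert comp[int(np.argmax(bc))] == hub_idx
        assert bc.max() > 2 * np.partition(bc, -2)[-2] + 1

    def test_baseline_hub_weak(self):
        _, base = make_state_covariances(20, 5, seed=0)
        off = np.delete(base[5], 5)
        assert np.max(np.abs(off)) <= 0.1


class TestSimulateSubject:
    SPEC = SyntheticCohortSpec(seed=3)

    def test_full_occupancy_matches_hub_covariance(self):
        spec = SyntheticCohortSpec(n_volumes=2000, noise_sd=0.05, seed=3)
        ts, states = simulate_subject(spec, 1.0, seed=11)
        assert states.all()
        hub_cov, _ = make_state_covariances(spec.n_nodes, spec.hub_index, spec.seed)
        sample = np.corrcoef(ts.data.T)
        assert np.max(np.abs(sample - hub_cov)) < 0.1

    def test_zero_occupancy_all_baseline(self):
        _, states = simulate_subject(self.SPEC, 0.0, seed=4)
        assert not states.any()

    def test_same_seed_bit_identical(self):
        a, sa = simulate_subject(self.SPEC, 0.4, seed=9)
        b, sb = simulate_subject(self.SPEC, 0.4, seed=9)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(sa, sb)

    def test_occupancy_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            simulate_subject(self.SPEC, 1.5, seed=0)

    def test_dwell_times_near_mean(self):
        spec = SyntheticCohortSpec(n_volumes=20000, state_dwell_mean_tr=30, seed=3)
        _, states = simulate_subject(spec, 0.5, seed=2)
        changes = np.flatnonzero(np.diff(states)) + 1
        dwells = np.diff(np.concatenate(([0], changes, [states.size])))
        assert abs(dwells.mean() - 30) < 5


class TestSimulateCohort:
    def test_shapes_and_score_range(self):
        series, truth = simulate_cohort(SyntheticCohortSpec(seed=0))
        assert len(series) == 20
        assert all(ts.data.shape == (260, 20) for ts in series)
        assert set(np.unique(truth.uls)) <= {0, 1, 2, 3, 4}
        for occ, states in zip(truth.occupancy, truth.states):
            assert occ == states.mean()

    def test_uls_marginal_matches_clinical_distribution(self):
        _, truth = simulate_cohort(SyntheticCohortSpec(seed=0))
        uls = truth.uls
        assert (uls == 0).sum() == 1  # none: 5%
        assert np.isin(uls, [1, 2]).sum() == 11  # mild/moderate: 55%
        assert np.isin(uls, [3, 4]).sum() == 8  # severe: 40%

    def test_negative_coupling_realized(self):
        _, truth = simulate_cohort(SyntheticCohortSpec(coupling_rho=-0.6, seed=0))
        rho = spearmanr(truth.occupancy, truth.uls).statistic
        assert rho < -0.4

    def test_zero_coupling_is_null(self):
        """With coupling_rho=0 the score is independent of occupancy: over
        100 seeds the |Spearman| stays within the sampling scatter expected
        at n=20 (sd ~0.23), i.e. below 0.45 in at least 90 runs and centered
        on zero."""
        rhos = []
        for seed in range(100):
            _, truth = simulate_cohort(
                SyntheticCohortSpec(coupling_rho=0.0, seed=seed)
            )
            rhos.append(spearmanr(truth.occupancy, truth.uls).statistic)
        rhos = np.array(rhos)
        assert (np.abs(rhos) < 0.45).sum() >= 90
        assert abs(rhos.mean()) < 0.1

    def test_reproducible(self):
        sa, ta = simulate_cohort(SyntheticCohortSpec(seed=5))
        sb, tb = simulate_cohort(SyntheticCohortSpec(seed=5))
        assert all(np.array_equal(a.data, b.data) for a, b in zip(sa, sb))
        assert np.array_equal(ta.uls, tb.uls)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ParameterError):
            simulate_cohort(SyntheticCohortSpec(n_subjects=4))

    def test_write_cohort_round_trip(self, tmp_path):
        from dynhub.io import read_manifest, read_timeseries

        spec = SyntheticCohortSpec(n_subjects=5, n_volumes=40, n_nodes=8, seed=1)
        series, truth = simulate_cohort(spec)
        manifest_path = write_cohort(series, truth, tmp_path / "cohort")
        manifest = read_manifest(manifest_path)
        assert manifest.n_subjects == 5
        back = read_timeseries(manifest.paths[0], spec.tr_seconds)
        np.testing.assert_allclose(back.data, series[0].data, atol=1e-8)
        np.testing.assert_array_equal(manifest.uls, truth.uls)


class TestAssignUls:
    def test_perfect_coupling_reverses_order(self, rng):
        occ = np.linspace(0.1, 0.9, 20)
        uls = assign_uls(occ, -1.0, rng)
        # monotone non-increasing in occupancy
        assert np.all(np.diff(uls[np.argsort(occ)]) <= 0)

    def test_generic_cohort_sizes(self, rng):
        for n in (5, 13, 20, 41):
            uls = assign_uls(np.linspace(0, 1, n), -0.5, rng)
            assert uls.size == n and uls.min() >= 0 and uls.max() <= 4
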