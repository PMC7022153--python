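import numpy as np
import pandas as pd
import pytest
from scipy import stats

import fcdev
from fcdev.synthetic import (
    SimulationConfig,
    generate_null_map,
    make_annotation_maps,
    nearest_correlation,
    plant_edge_trajectories,
    sample_cohort_design,
    simulate_edge_fc,
    simulate_scan_timeseries,
)


class TestCohortDesign:
    def test_row_bounds_and_coverage(self):
        cfg = SimulationConfig(n_subjects=100, scans_per_subject_probs=(0.4, 0.4, 0.2), seed=7)
        meta = sample_cohort_design(cfg)
        assert 100 <= len(meta) <= 300
        assert meta["subject_id"].nunique() == 100
        assert meta["age"].between(14, 26).all()

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(n_subjects=50, seed=3)
        pd.testing.assert_frame_equal(sample_cohort_design(cfg), sample_cohort_design(cfg))

    def test_expected_scan_count_matches_closed_form(self):
        probs = (0.4, 0.4, 0.2)
        cfg = SimulationConfig(n_subjects=50, scans_per_subject_probs=probs)
        expect = 50 * sum(k * p for k, p in zip((1, 2, 3), probs))
        counts = [len(sample_cohort_design(cfg, seed=s)) for s in range(200)]
        var_one = sum(k**2 * p for k, p in zip((1, 2, 3), probs)) - (expect / 50) ** 2
        se = np.sqrt(50 * var_one / 200)
        assert abs(np.mean(counts) - expect) < 3 * se

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            sample_cohort_design(SimulationConfig(n_subjects=1))

    def test_invalid_probs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(scans_per_subject_probs=(0.5, 0.5, 0.5))


class TestPlantedTrajectories:
    def test_noiseless_extreme_targets_realize_exactly(self, small_parc):
        n = small_parc.n_regions
        for sign in (1.0, -1.0):
            cfg = SimulationConfig(
                n_cortical=16, n_subcortical=4, mi_targets=(sign,) * n, slope_noise_sd=0.0
            )
            truth = plant_edge_trajectories(small_parc, cfg)
            assert np.allclose(truth.true_mi, sign)

    def test_realized_mi_recomputable_exactly(self, small_cohort):
        truth = small_cohort.truth
        again = truth.recompute_mi(small_cohort.parcellation.n_regions)
        assert np.array_equal(truth.true_mi, again, equal_nan=True)

    def test_mixed_targets_sign_recovery_across_seeds(self, small_parc):
        hits = total = 0
        targets = np.where(np.arange(20) // 2 % 2 == 0, 0.6, -0.6)
        cfg = SimulationConfig(n_cortical=16, n_subcortical=4, mi_targets=tuple(targets))
        for seed in range(50):
            truth = plant_edge_trajectories(small_parc, cfg, seed=seed)
            hits += np.sum(np.sign(truth.true_mi) == np.sign(targets))
            total += len(targets)
        assert hits / total >= 0.90

    def test_target_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(mi_targets=(1.5,) * 40)


class TestEdgeFCSimulation:
    def test_deterministic_limit_exactly_linear_in_age(self, small_parc):
        cfg = SimulationConfig(
            n_cortical=16, n_subcortical=4, n_subjects=30, noise_sd=0.0,
            subject_sd=0.0, motion_gamma0=0.0, motion_gamma_slope=0.0,
            beta_sex=0.0, beta_site=0.0, slope_scale=0.002, seed=5,
        )
        meta = sample_cohort_design(cfg)
        truth = plant_edge_trajectories(small_parc, cfg)
        ds, _ = simulate_edge_fc(truth, meta, cfg)
        age = ds.meta["age"].to_numpy() - 14
        for k in range(0, ds.n_edges, 7):
            resid = np.polyval(np.polyfit(age, ds.fc[k], 1), age) - ds.fc[k]
            assert np.abs(resid).max() < 1e-12

    def test_motion_coupling_drives_positive_qcfc(self):
        cfg = SimulationConfig(
            n_subjects=120, n_cortical=16, n_subcortical=4,
            motion_gamma0=0.3, motion_gamma_slope=0.0, seed=13,
        )
        c = fcdev.simulate_cohort(cfg)
        rep = fcdev.qcfc(c.dataset)
        assert rep.median_qcfc > 0

    def test_distance_dependent_coupling_detected(self):
        cfg = SimulationConfig(
            n_subjects=120, n_cortical=24, n_subcortical=4,
            motion_gamma0=0.1, motion_gamma_slope=0.003, seed=17,
        )
        c = fcdev.simulate_cohort(cfg)
        dists = fcdev.edge_distance(c.parcellation, c.dataset.edges)
        rep = fcdev.qcfc(c.dataset, distances=dists)
        assert rep.distance_dependence > 0

    def test_bitwise_reproducible(self):
        cfg = SimulationConfig(n_subjects=20, n_cortical=8, n_subcortical=2, seed=3)
        a = fcdev.simulate_cohort(cfg)
        b = fcdev.simulate_cohort(cfg)
        assert np.array_equal(a.dataset.fc, b.dataset.fc)
        assert np.array_equal(a.truth.true_mi, b.truth.true_mi, equal_nan=True)

    def test_fc_clipped_to_valid_range(self):
        cfg = SimulationConfig(n_subjects=20, n_cortical=8, n_subcortical=2,
                               noise_sd=1.5, seed=3)
        c = fcdev.simulate_cohort(cfg)
        assert np.abs(c.dataset.fc).max() <= 0.999


class TestTimeSeriesSimulation:
    def test_psd_input_unchanged(self):
        c = np.array([[1.0, 0.3], [0.3, 1.0]])
        assert np.abs(nearest_correlation(c) - c).max() < 1e-12

    def test_psd_repair_is_idempotent(self):
        bad = np.full((3, 3), -0.9) + 1.9 * np.eye(3)
        rep = nearest_correlation(bad)
        assert np.linalg.eigvalsh(rep).min() >= -1e-12
        assert np.allclose(np.diag(rep), 1.0)
        assert np.abs(nearest_correlation(rep) - rep).max() < 1e-9

    def test_sample_fc_converges_to_target(self):
        ts, _ = simulate_scan_timeseries(np.eye(2), n_volumes=10_000, seed=3)
        r = fcdev.fc_matrix(ts)[0, 1]
        assert abs(r) < 0.05

    def test_motion_events_leave_trace_and_inflate_fc(self):
        target = np.eye(4)
        clean, _ = simulate_scan_timeseries(target, 300, seed=5)
        noisy, trace = simulate_scan_timeseries(target, 300, seed=5, n_motion_events=30,
                                                motion_amp=3.0)
        fd = fcdev.framewise_displacement(trace)
        assert fd.max_fd > fcdev.framewise_displacement(
            simulate_scan_timeseries(target, 300, seed=5)[1]).max_fd
        mean_off = lambda m: m[np.triu_indices(4, 1)].mean()
        assert mean_off(fcdev.fc_matrix(noisy)) > mean_off(fcdev.fc_matrix(clean))

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            simulate_scan_timeseries(np.array([[1.0, 0.5], [0.4, 1.0]]))


class TestAnnotationMaps:
    def test_full_coupling_rank_equal_to_true_mi(self, small_cohort):
        cfg = SimulationConfig(n_cortical=16, n_subcortical=4, map_coupling=(1.0,))
        maps = make_annotation_maps(small_cohort.truth, small_cohort.parcellation, cfg)
        ctx = small_cohort.parcellation.cortical_index
        rho = stats.spearmanr(maps[0].values[ctx], small_cohort.truth.true_mi[ctx]).statistic
        assert rho == pytest.approx(1.0)

    @pytest.mark.parametrize("coupling,tol", [(0.0, 0.03), (-0.56, 0.05)])
    def test_mean_recovered_coupling(self, coupling, tol):
        parc = fcdev.make_parcellation(60, 4, seed=1)
        cfg = SimulationConfig(n_cortical=60, n_subcortical=4, map_coupling=(coupling,))
        truth = plant_edge_trajectories(parc, cfg)
        ctx = parc.cortical_index
        mi_ctx = truth.true_mi[ctx]
        rhos = []
        for seed in range(100):
            m = make_annotation_maps(truth, parc, cfg, seed=seed)
            rhos.append(stats.spearmanr(m[0].values[ctx], mi_ctx).statistic)
        assert abs(np.mean(rhos) - coupling) < tol

    def test_invalid_coupling_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(map_coupling=(1.2,))

    def test_categorical_map_included(self, small_cohort):
        kinds = [m.kind for m in small_cohort.annotation_maps]
        assert kinds.count("categorical") == 1


class TestNullMaps:
    def _neighbor_corr(self, parc, vals):
        # within the left hemisphere (maps are bilaterally symmetric, so a
        # cross-hemisphere neighbour can be a region's own mirror twin)
        left = parc.cortical_index[parc.hemisphere[parc.cortical_index] == "L"]
        xyz = parc.sphere_coords()[left]
        d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=2) + 1e9 * np.eye(len(left))
        nn = d.argmin(axis=1)
        v = vals[left]
        return np.corrcoef(v, v[nn])[0, 1]

    def test_smoothness_controls_neighbor_correlation(self):
        parc = fcdev.make_parcellation(80, 0, seed=1)
        rough = np.mean([self._neighbor_corr(parc, generate_null_map(parc, 0.5, s).values)
                         for s in range(30)])
        smooth = np.mean([self._neighbor_corr(parc, generate_null_map(parc, 40.0, s).values)
                          for s in range(30)])
        assert abs(rough) < 0.2
        assert smooth > 0.25
        assert smooth > rough + 0.2

    def test_same_seed_identical(self, small_parc):
        a = generate_null_map(small_parc, 20.0, seed=5)
        b = generate_null_map(small_parc, 20.0, seed=5)
        assert np.array_equal(a.values, b.values, equal_nan=True)

    def test_invalid_smoothness_rejected(self, small_parc):
        with pytest.raises(ValueError):
            generate_null_map(small_parc, 0.0, seed=1)
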