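import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import fcdev
from fcdev.growth import EdgeGrowthEstimates
from fcdev.maturation import (
    bh_fdr,
    classify_modes,
    generate_spins,
    half_split_stability,
    maturational_index,
    spearman_rho,
    spin_test_map_correlation,
    spin_test_mi,
)
from fcdev.parcellation import edge_index


class TestSpearman:
    def test_monotone_sequences(self):
        x = np.arange(10.0)
        assert spearman_rho(x, 2 * x + 1) == pytest.approx(1.0)
        assert spearman_rho(x, -x) == pytest.approx(-1.0)

    def test_midrank_tie_handling(self):
        # ranks of x are [1, 2.5, 2.5, 4]; hand Pearson on ranks = 0.9487
        assert spearman_rho([1, 2, 2, 3], [1, 2, 3, 4]) == pytest.approx(0.9487, abs=1e-4)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBhFdr:
    def test_hand_step_up_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.5])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_degenerate_vectors(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 0.0])

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_step_up(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-12, 1.0, size=rng.integers(1, 40))
        q = bh_fdr(p)
        # brute force: q_(i) = min_{j >= i} p_(j) * n / j
        order = np.argsort(p, kind="stable")
        n = len(p)
        staged = p[order] * n / np.arange(1, n + 1)
        brute_sorted = np.minimum.accumulate(staged[::-1])[::-1]
        brute = np.empty(n)
        brute[order] = np.minimum(brute_sorted, 1.0)
        assert np.allclose(q, brute, atol=1e-12)
        assert (q >= p - 1e-12).all()


def _estimates_from_maps(parc, fc14_fn, delta_fn, seed=0):
    """EdgeGrowthEstimates with fc14/delta set by functions of edge draws."""
    edges = edge_index(parc.n_regions)
    rng = np.random.default_rng(seed)
    fc14 = rng.uniform(0.1, 0.9, len(edges))
    fc14 = fc14_fn(fc14)
    delta = delta_fn(fc14)
    e = len(edges)
    return EdgeGrowthEstimates(
        edges, fc14, delta, delta / 12.0, np.full(e, 0.01), np.full(e, 0.5),
        np.ones(e, bool),
    )


class TestMaturationalIndex:
    def test_proportional_change_gives_conservative_unity(self, small_parc):
        est = _estimates_from_maps(small_parc, lambda b: b, lambda b: 2.0 * b)
        mi = maturational_index(est, small_parc)
        assert np.allclose(mi.table["mi"], 1.0)

    def test_compensatory_change_gives_disruptive_unity(self, small_parc):
        est = _estimates_from_maps(small_parc, lambda b: b, lambda b: 0.3 - b)
        mi = maturational_index(est, small_parc)
        assert np.allclose(mi.table["mi"], -1.0)

    def test_min_edges_marks_indeterminate(self, small_parc):
        est = _estimates_from_maps(small_parc, lambda b: b, lambda b: 2 * b)
        mi = maturational_index(est, small_parc, min_edges=10_000)
        assert mi.table["mi"].isna().all()

    def test_rank_invariance_under_monotone_transforms(self, small_parc):
        est = _estimates_from_maps(small_parc, lambda b: b, lambda b: 0.2 - 0.5 * b + 0.01 * b**2)
        mi1 = maturational_index(est, small_parc).table["mi"]
        warped = EdgeGrowthEstimates(
            est.edges, np.exp(3 * est.fc14), np.tanh(est.delta), est.slope,
            est.slope_se, est.slope_p, est.ok,
        )
        mi2 = maturational_index(warped, small_parc).table["mi"]
        assert np.allclose(mi1, mi2)

    def test_subset_restricts_edge_counts(self, small_parc):
        est = _estimates_from_maps(small_parc, lambda b: b, lambda b: 2 * b)
        n_ctx = small_parc.n_cortical
        cc = maturational_index(est, small_parc, subset="cc", min_edges=3)
        tab = cc.table
        assert (tab.loc[tab["cortical"], "n_edges"] == n_ctx - 1).all()
        assert (tab.loc[~tab["cortical"], "n_edges"] == 0).all()

    def test_scale_invariance_delta_vs_annual_slope(self, small_cohort):
        est = fcdev.fit_all_edges(small_cohort.dataset)
        mi_delta = maturational_index(est, small_cohort.parcellation).table["mi"]
        est_slope = EdgeGrowthEstimates(
            est.edges, est.fc14, est.slope, est.slope, est.slope_se, est.slope_p, est.ok
        )
        mi_slope = maturational_index(est_slope, small_cohort.parcellation).table["mi"]
        assert np.allclose(mi_delta.to_numpy(), mi_slope.to_numpy(), equal_nan=True)


class TestSpins:
    def test_identity_spin_when_requested(self, small_parc):
        spins = generate_spins(small_parc, 3, seed=1, include_identity=True)
        assert np.array_equal(spins.perms[0], np.arange(small_parc.n_cortical))

    def test_rows_are_bijections(self, small_parc):
        spins = generate_spins(small_parc, 50, seed=2)
        target = np.arange(small_parc.n_cortical)
        for row in spins.perms:
            assert np.array_equal(np.sort(row), target)

    def test_hemispheres_never_mix(self, small_parc):
        spins = generate_spins(small_parc, 100, seed=3)
        hemi = small_parc.hemisphere[small_parc.cortical_index]
        for row in spins.perms:
            assert np.array_equal(hemi[row], hemi)

    def test_deterministic_given_seed(self, small_parc):
        a = generate_spins(small_parc, 10, seed=4)
        b = generate_spins(small_parc, 10, seed=4)
        assert np.array_equal(a.perms, b.perms)

    def test_missing_sphere_coordinates_rejected(self):
        from test_connectivity import _mini_parc

        parc = _mini_parc()
        broken = parc.table.copy()
        broken.loc[broken.cls == "cortical", "region"] = ["c1", "c2"]
        # strip a cortical spherical coordinate -> construction must fail
        broken.loc[0, "sx"] = np.nan
        with pytest.raises(ValueError):
            fcdev.Parcellation(broken)


class TestSpinTestMapCorrelation:
    def test_self_correlation_attains_minimal_p(self):
        # at a fine enough lattice no random rotation reproduces the
        # identity permutation, so map-vs-itself attains the p floor
        parc = fcdev.make_parcellation(200, 0, seed=5)
        spins = generate_spins(parc, 999, seed=6)
        identity = np.arange(parc.n_cortical)
        assert not any(np.array_equal(row, identity) for row in spins.perms)
        m = fcdev.generate_null_map(parc, 20.0, seed=7)
        rho, p = spin_test_map_correlation(m, m, spins, parc)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(1.0 / 1000.0)

    def test_p_value_floor(self):
        parc = fcdev.make_parcellation(20, 0, seed=8)
        spins = generate_spins(parc, 19, seed=9)
        for s in range(5):
            a = fcdev.generate_null_map(parc, 15.0, seed=10 + s)
            b = fcdev.generate_null_map(parc, 15.0, seed=100 + s)
            _, p = spin_test_map_correlation(a, b, spins, parc)
            assert 1.0 / 20.0 <= p <= 1.0

    def test_antisymmetric_under_map_negation(self):
        parc = fcdev.make_parcellation(30, 0, seed=11)
        spins = generate_spins(parc, 200, seed=12)
        a = fcdev.generate_null_map(parc, 15.0, seed=13)
        b = fcdev.generate_null_map(parc, 15.0, seed=14)
        rho1, p1 = spin_test_map_correlation(a, b, spins, parc)
        neg = fcdev.AnnotationMap("neg", -np.asarray(b.values))
        rho2, p2 = spin_test_map_correlation(a, neg, spins, parc)
        assert rho2 == pytest.approx(-rho1)
        assert p2 == pytest.approx(p1)

    def test_fast_path_matches_explicit_shuffling(self):
        # same permutations -> identical null correlations, computed two ways
        parc = fcdev.make_parcellation(8, 0, seed=15)
        spins = generate_spins(parc, 50, seed=16)
        ctx = parc.cortical_index
        rng = np.random.default_rng(17)
        a = rng.normal(size=8)
        b = rng.normal(size=8)
        ra = stats.rankdata(a)
        rb = stats.rankdata(b)
        spun = ra[spins.perms]
        spun_c = spun - spun.mean(axis=1, keepdims=True)
        rbc = rb - rb.mean()
        fast = (spun_c @ rbc) / np.sqrt((spun_c**2).sum(1) * (rbc @ rbc))
        slow = np.array(
            [stats.spearmanr(a[perm], b).statistic for perm in spins.perms]
        )
        assert np.array_equal(fast, slow) or np.allclose(fast, slow, atol=1e-14)

    def test_constant_map_rejected(self):
        parc = fcdev.make_parcellation(10, 0, seed=18)
        spins = generate_spins(parc, 10, seed=19)
        flat = fcdev.AnnotationMap("flat", np.zeros(10))
        wavy = fcdev.generate_null_map(parc, 15.0, seed=20)
        with pytest.raises(ValueError):
            spin_test_map_correlation(flat, wavy, spins, parc)


class TestSpinTestMi:
    def test_flat_change_map_is_indeterminate(self, small_parc):
        est = _estimates_from_maps(small_parc, lambda b: b, lambda b: np.zeros_like(b))
        spins = generate_spins(small_parc, 20, seed=21)
        assert np.isnan(spin_test_mi(est, small_parc, 0, spins))

    def test_subcortical_region_unsupported(self, small_parc):
        est = _estimates_from_maps(small_parc, lambda b: b, lambda b: 2 * b)
        spins = generate_spins(small_parc, 20, seed=22)
        sub = int(small_parc.subcortical_index[0])
        with pytest.raises(ValueError):
            spin_test_mi(est, small_parc, sub, spins)

    def test_strong_coupling_detected(self):
        parc = fcdev.make_parcellation(40, 0, seed=23)
        est = _estimates_from_maps(parc, lambda b: b, lambda b: 2 * b + 0.001)
        spins = generate_spins(parc, 199, seed=24)
        p = spin_test_mi(est, parc, 0, spins)
        assert p < 0.05


class TestClassifyModes:
    def _mi_result(self, mi, p_spin, cortical=True):
        tab = pd.DataFrame(
            {
                "region": [f"r{i}" for i in range(len(mi))],
                "cortical": cortical,
                "mi": mi,
                "n_edges": 20,
                "p_param": p_spin,
                "p_spin": p_spin,
            }
        )
        return fcdev.MIResult(table=tab)

    def test_sign_and_significance_labels(self):
        mi = self._mi_result([0.5, -0.3, 0.0], [0.001, 0.5, 0.9])
        out = classify_modes(mi, alpha=0.05).table
        assert list(out["mode"]) == ["conservative", "disruptive", "indeterminate"]
        assert out["significant"].tolist() == [True, False, False]

    def test_q_values_within_family_dominate_p(self):
        mi = self._mi_result([0.4, 0.2, -0.1, -0.5], [0.01, 0.02, 0.03, 0.5])
        out = classify_modes(mi).table
        assert np.allclose(out["q"], [0.04, 0.04, 0.04, 0.5])


class TestHalfSplitStability:
    def test_splits_are_subject_disjoint_and_reproducible(self, small_cohort):
        r1 = half_split_stability(small_cohort.dataset, small_cohort.parcellation, 3, seed=1)
        r2 = half_split_stability(small_cohort.dataset, small_cohort.parcellation, 3, seed=1)
        assert np.array_equal(r1, r2)
        assert len(r1) == 3

    def test_strong_signal_yields_stable_mi_maps(self):
        targets = tuple(np.where(np.arange(28) // 2 % 2 == 0, 0.8, -0.8))
        cfg = fcdev.SimulationConfig(
            n_subjects=120, n_cortical=24, n_subcortical=4, mi_targets=targets, seed=43,
        )
        c = fcdev.simulate_cohort(cfg)
        r = half_split_stability(c.dataset, c.parcellation, 6, seed=2)
        assert np.median(r) >= 0.6

    def test_zero_splits_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            half_split_stability(small_cohort.dataset, small_cohort.parcellation, 0, seed=1)

    def test_too_few_subjects_rejected(self, small_cohort):
        ds = small_cohort.dataset
        few = ds.meta["subject_id"].isin(ds.meta["subject_id"].unique()[:4])
        sub = ds.subset_scans(np.flatnonzero(few.to_numpy()))
        with pytest.raises(ValueError):
            half_split_stability(sub, small_cohort.parcellation, 2, seed=1)
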