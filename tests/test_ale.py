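import math

import numpy as np
import pytest

from alemeta.ale import (
    AleParams,
    NullDistribution,
    ale_map,
    bh_reject,
    build_null,
    cluster_extent_filter,
    gaussian_kernel_map,
    p_value_map,
    sigma_from_fwhm,
    threshold_map,
)
from alemeta.corpus_io import Focus

from .conftest import make_experiment


class TestKernel:
    def test_sigma_closed_form(self):
        # FWHM = 2 sqrt(2 ln 2) sigma
        assert sigma_from_fwhm(10.0) == pytest.approx(10.0 / 2.3548200450309493, abs=1e-12)
        assert sigma_from_fwhm(10.0) == pytest.approx(4.246609001440095, abs=1e-12)

    def test_value_at_half_fwhm_is_half_peak(self, grid_1mm):
        k = gaussian_kernel_map(Focus(0, 0, 0), 10.0, grid_1mm)
        peak = grid_1mm.nearest_voxel((0, 0, 0))
        at_5mm = grid_1mm.nearest_voxel((5, 0, 0))
        # renormalization rescales both values equally, so the ratio is
        # exactly the pre-normalization half-maximum property
        assert k.values[at_5mm] / k.values[peak] == pytest.approx(0.5, abs=1e-12)

    def test_kernel_sums_to_one_over_mask(self, grid16):
        k = gaussian_kernel_map(Focus(3, -5, 7), 10.0, grid16)
        assert k.values[grid16.mask].sum() == pytest.approx(1.0, abs=1e-9)

    def test_peak_at_focus_voxel(self, grid16):
        k = gaussian_kernel_map(Focus(4.6, -2.2, 6.1), 10.0, grid16)
        assert np.unravel_index(np.argmax(k.values), k.shape) == grid16.nearest_voxel((4.6, -2.2, 6.1))

    def test_bad_fwhm_rejected(self, grid16):
        with pytest.raises(ValueError, match="fwhm"):
            gaussian_kernel_map(Focus(0, 0, 0), 0.0, grid16)

    def test_out_of_mask_focus_rejected(self, grid16):
        with pytest.raises(ValueError, match="outside"):
            gaussian_kernel_map(Focus(500, 0, 0), 10.0, grid16)


class TestAleMap:
    def test_single_focus_equals_kernel(self, grid16):
        exp = make_experiment("e1", [(2, 2, 2)])
        params = AleParams(seed=0)
        a = ale_map([exp], params, grid16)
        k = gaussian_kernel_map(Focus(2, 2, 2), params.fwhm, grid16)
        assert np.allclose(a.values, k.values, atol=1e-15)

    def test_two_identical_experiments_union_closed_form(self, grid16):
        exp1 = make_experiment("e1", [(0, 0, 0)])
        exp2 = make_experiment("e2", [(0, 0, 0)])
        params = AleParams(seed=0)
        k = gaussian_kernel_map(Focus(0, 0, 0), params.fwhm, grid16).values
        a = ale_map([exp1, exp2], params, grid16)
        assert np.allclose(a.values, 1 - (1 - k) ** 2, atol=1e-15)

    def test_union_matches_inclusion_exclusion(self, grid16):
        """Brute-force inclusion-exclusion over experiments' MA maps."""
        from itertools import combinations

        rng = np.random.default_rng(3)
        exps = [
            make_experiment(f"e{i}", rng.uniform(-10, 10, size=(2, 3)).tolist())
            for i in range(3)
        ]
        params = AleParams(seed=0)
        a = ale_map(exps, params, grid16)
        ma = []
        for e in exps:
            prod = np.ones(grid16.shape)
            for f in e.foci:
                prod *= 1 - gaussian_kernel_map(f, params.fwhm, grid16).values
            ma.append(1 - prod)
        sample = [(2, 3, 4), (8, 8, 8), (15, 0, 1), (7, 12, 9), (0, 0, 0)]
        for v in sample:
            ie = 0.0
            for r in range(1, 4):
                for combo in combinations(range(3), r):
                    term = np.prod([ma[i][v] for i in combo])
                    ie += (-1) ** (r + 1) * term
            assert a.values[v] == pytest.approx(ie, abs=1e-12)

    def test_monotone_in_experiments(self, grid16):
        rng = np.random.default_rng(8)
        exps = [
            make_experiment(f"e{i}", rng.uniform(-12, 12, size=(3, 3)).tolist())
            for i in range(4)
        ]
        params = AleParams(seed=0)
        prev = np.zeros(grid16.shape)
        for n in range(1, 5):
            cur = ale_map(exps[:n], params, grid16).values
            assert np.all(cur >= prev - 1e-15)
            prev = cur

    def test_invariant_under_reordering(self, grid16):
        rng = np.random.default_rng(9)
        exps = [
            make_experiment(f"e{i}", rng.uniform(-12, 12, size=(3, 3)).tolist())
            for i in range(3)
        ]
        params = AleParams(seed=0)
        a = ale_map(exps, params, grid16).values
        shuffled = [exps[2], exps[0], exps[1]]
        shuffled[0].foci = shuffled[0].foci[::-1]
        b = ale_map(shuffled, params, grid16).values
        assert np.allclose(a, b, atol=1e-15)

    def test_range_and_mask(self, grid16):
        exp = make_experiment("e", [(0, 0, 0), (4, 4, 4)])
        a = ale_map([exp], AleParams(seed=0), grid16)
        assert np.all(a.values >= 0) and np.all(a.values < 1)

    def test_per_focus_union_variant_pools_foci(self, grid16):
        # with grouping off, two experiments behave like one pooled one
        e1 = make_experiment("e1", [(0, 0, 0)])
        e2 = make_experiment("e2", [(4, 0, 0)])
        pooled = make_experiment("p", [(0, 0, 0), (4, 0, 0)])
        params = AleParams(group_by_experiment=False, seed=0)
        a = ale_map([e1, e2], params, grid16).values
        b = ale_map([pooled], params, grid16).values
        assert np.allclose(a, b, atol=1e-15)

    def test_empty_input_rejected(self, grid16):
        with pytest.raises(ValueError):
            ale_map([], AleParams(seed=0), grid16)


class TestNull:
    def test_p_value_conventions(self):
        null = NullDistribution(np.linspace(0.0, 0.1, 199))
        n = null.n_samples
        # above the null maximum: floor convention 1/(n+1)
        assert null.p_values(np.array([1.0]))[0] == pytest.approx(1 / (n + 1))
        # an observed 0 is never significant
        assert null.p_values(np.array([0.0]))[0] == 1.0

    def test_p_value_monotone_non_increasing(self):
        rng = np.random.default_rng(0)
        null = NullDistribution(rng.random(500))
        obs = np.sort(rng.random(100))
        p = null.p_values(obs)
        assert np.all(np.diff(p) <= 1e-15)

    def test_deterministic_given_seed(self, grid16):
        exps = [make_experiment("e", [(0, 0, 0), (5, 5, 5)])]
        params = AleParams(n_permutations=100, seed=21)
        a = build_null(exps, params, grid16)
        b = build_null(exps, params, grid16)
        assert np.array_equal(a.values, b.values)

    def test_null_sample_size(self, grid16):
        exps = [make_experiment("e", [(0, 0, 0)])]
        params = AleParams(n_permutations=100, seed=2)
        null = build_null(exps, params, grid16)
        assert null.n_samples == 100 * int(grid16.mask.sum())


class TestThreshold:
    def test_bh_hand_example(self):
        # sorted p vs q*k/m: 0.01<=0.0125, 0.02<=0.025, 0.04>0.0375, 0.9>0.05
        reject = bh_reject(np.array([0.01, 0.02, 0.04, 0.9]), 0.05)
        assert reject.tolist() == [True, True, False, False]

    def test_bh_agrees_with_independent_stepup(self):
        def hand_bh(p, q):
            m = len(p)
            order = np.argsort(p, kind="stable")
            sorted_p = p[order]
            below = sorted_p <= q * (np.arange(1, m + 1) / m)
            out = np.zeros(m, dtype=bool)
            if below.any():
                k = int(np.max(np.flatnonzero(below)))
                out[order[: k + 1]] = True
            return out

        rng = np.random.default_rng(17)
        for _ in range(100):
            p = rng.random(rng.integers(1, 40))
            assert np.array_equal(bh_reject(p, 0.05), hand_bh(p, 0.05))

    def test_cluster_extent_rule_strict_100mm3(self, grid32):
        # 2 mm grid: 12 voxels = 96 mm^3 (removed), 13 voxels = 104 mm^3 (kept)
        binary = np.zeros(grid32.shape, dtype=bool)
        binary[2, 2, 2:14] = True          # 12-voxel line component
        binary[20, 20, 2:15] = True        # 13-voxel line component
        kept = cluster_extent_filter(binary, grid32, 100.0, connectivity=26)
        assert kept[2, 2, 5] == False
        assert kept[20, 20, 5] == True
        assert kept.sum() == 13

    def test_connectivity_switch(self, grid32):
        binary = np.zeros(grid32.shape, dtype=bool)
        # two diagonal voxels: one component at 26-connectivity, two at 6
        binary[4, 4, 4] = binary[5, 5, 5] = True
        from scipy import ndimage

        from alemeta.ale import _connectivity_structure

        assert ndimage.label(binary, _connectivity_structure(26))[1] == 1
        assert ndimage.label(binary, _connectivity_structure(6))[1] == 2

    def test_no_signal_yields_empty_map(self, grid16):
        ale = grid16.like(np.zeros(grid16.shape))
        null = NullDistribution(np.linspace(0.001, 0.2, 500))
        params = AleParams(n_permutations=100, seed=0)
        out = threshold_map(ale, null, params)
        assert out.values.sum() == 0

    def test_planted_signal_survives(self, grid16):
        exps = [make_experiment(f"e{i}", [(0, 0, 0)]) for i in range(8)]
        params = AleParams(n_permutations=100, min_cluster_mm3=0.0, seed=4)
        a = ale_map(exps, params, grid16)
        null = build_null(exps, params, grid16)
        out = threshold_map(a, null, params)
        assert out.values[grid16.nearest_voxel((0, 0, 0))] == 1.0


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"fwhm": -1.0},
            {"n_permutations": 10},
            {"q_fdr": 0.0},
            {"q_fdr": 1.0},
            {"min_cluster_mm3": -5.0},
            {"connectivity": 18},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AleParams(**kwargs)
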