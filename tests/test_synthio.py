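"""Synthetic-data generators: ground truth, determinism, preconditions."""

import numpy as np
import pytest

from cytomech import mtdyn
from cytomech.elastics import fttc_inverse
from cytomech.quant3d import fit_gain_curve
from cytomech.synthio import (
    DipoleSpec,
    MTSimParams,
    StackSimParams,
    simulate_cohort,
    simulate_confocal_stack,
    simulate_intensity_table,
    simulate_mt_traces,
    simulate_traction_scene,
)

from conftest import relative_l2


class TestTractionScene:
    def test_noiseless_displacement_is_forward_solution(self, gel_soft, grid64, compact_dipole_scene):
        from cytomech.elastics import forward_solve

        truth, disp, _ = compact_dipole_scene
        np.testing.assert_array_equal(disp.u, forward_solve(truth, gel_soft).u)

    def test_zero_dipoles(self, gel_soft, grid64):
        truth, disp, _ = simulate_traction_scene([], gel_soft, grid64)
        assert np.all(truth.t == 0)
        assert np.all(disp.u == 0)

    def test_moment_trace_oracle(self, grid64, reference_dipole_scene):
        # independent oracle: discrete first-moment sum over the whole grid
        truth, _, _ = reference_dipole_scene
        X, Y = grid64.meshgrid()
        trace = (X * truth.t[..., 0] + Y * truth.t[..., 1]).sum() * grid64.cell_area
        assert trace == pytest.approx(-100.0 * 20.0, rel=1e-6)

    def test_net_force_zero(self, reference_dipole_scene, grid64):
        truth, _, _ = reference_dipole_scene
        dA = grid64.cell_area
        net = np.linalg.norm(truth.t.sum(axis=(0, 1)) * dA)
        total = np.hypot(truth.t[..., 0], truth.t[..., 1]).sum() * dA
        assert net < 1e-9 * total

    def test_pole_force_magnitude(self, grid64, reference_dipole_scene):
        # each pole integrates to 100 pN: half-plane sum of |t_x| dA
        truth, _, _ = reference_dipole_scene
        left = truth.t[:, :32, 0].sum() * grid64.cell_area
        assert left == pytest.approx(100.0, rel=1e-6)

    def test_forward_consistency_inverse_recovers(self, gel_soft, grid64, compact_dipole_scene):
        truth, disp, _ = compact_dipole_scene
        recovered = fttc_inverse(disp, gel_soft, reg_lambda=0.0)
        assert relative_l2(recovered.t, truth.t) < 0.05

    def test_determinism(self, gel_soft, grid64):
        dip = DipoleSpec((31.5, 31.5), 0.7, 80.0, 12.0, 2.0)
        a = simulate_traction_scene([dip], gel_soft, grid64, noise_sd=0.01, seed=42)
        b = simulate_traction_scene([dip], gel_soft, grid64, noise_sd=0.01, seed=42)
        np.testing.assert_array_equal(a[0].t, b[0].t)
        np.testing.assert_array_equal(a[1].u, b[1].u)
        np.testing.assert_array_equal(a[2].polygon, b[2].polygon)

    def test_mask_encloses_poles(self, grid64, reference_dipole_scene):
        truth, _, mask = reference_dipole_scene
        raster = mask.raster_on(grid64)
        # traction magnitude peaks must lie inside the mask
        peak = np.unravel_index(np.argmax(np.hypot(truth.t[..., 0], truth.t[..., 1])), grid64.shape)
        assert raster[peak]

    def test_pole_outside_grid_rejected(self, gel_soft, grid64):
        dip = DipoleSpec((60.0, 31.5), 0.0, 100.0, 20.0, 2.0)
        with pytest.raises(ValueError, match="outside the grid"):
            simulate_traction_scene([dip], gel_soft, grid64)

    def test_negative_noise_rejected(self, gel_soft, grid64):
        with pytest.raises(ValueError, match="noise_sd"):
            simulate_traction_scene([], gel_soft, grid64, noise_sd=-1.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(separation=-1.0),
            dict(force_magnitude=-5.0),
            dict(patch_radius=0.0),
        ],
    )
    def test_dipole_invariants(self, kwargs):
        base = dict(center=(0.0, 0.0), axis_angle=0.0, force_magnitude=10.0,
                    separation=5.0, patch_radius=1.0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            DipoleSpec(**base)


class TestMTTraces:
    def test_zero_dynamicity_constant(self):
        traces = simulate_mt_traces(MTSimParams(n_traces=5, dynamicity=0.0, seed=1))
        for tr in traces:
            assert np.all(tr.lengths == tr.lengths[0])
            assert mtdyn.max_length_change(tr) == 0.0

    def test_dynamicity_orders_medians(self):
        slow = simulate_mt_traces(MTSimParams(n_traces=40, dynamicity=0.02, seed=7))
        fast = simulate_mt_traces(MTSimParams(n_traces=40, dynamicity=0.15, seed=8))
        med_slow = np.median([mtdyn.max_length_change(t) for t in slow])
        med_fast = np.median([mtdyn.max_length_change(t) for t in fast])
        assert med_fast > med_slow

    def test_duration_convention(self):
        traces = simulate_mt_traces(MTSimParams(n_traces=1, n_frames=10, frame_interval=3.0))
        assert traces[0].n_frames == 10
        assert traces[0].duration == pytest.approx(27.0)

    def test_positive_lengths_under_high_dynamicity(self):
        traces = simulate_mt_traces(
            MTSimParams(n_traces=20, dynamicity=1.5, base_length=1.0, floor=0.1, seed=3)
        )
        for tr in traces:
            assert np.all(tr.lengths > 0)

    def test_determinism(self):
        p = MTSimParams(n_traces=10, dynamicity=0.1, seed=9)
        a = simulate_mt_traces(p)
        b = simulate_mt_traces(p)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.lengths, y.lengths)

    def test_base_length_recovery(self):
        big = simulate_mt_traces(MTSimParams(n_traces=40, base_length=12.0, dynamicity=0.02, seed=5))
        small = simulate_mt_traces(MTSimParams(n_traces=40, base_length=6.0, dynamicity=0.02, seed=6))
        med_big = np.median(list(mtdyn.longest_mt_per_cell(big).values()))
        med_small = np.median(list(mtdyn.longest_mt_per_cell(small).values()))
        assert med_big == pytest.approx(12.0, rel=0.10)
        assert med_small == pytest.approx(6.0, rel=0.10)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            MTSimParams(n_traces=5, n_frames=1)
        with pytest.raises(ValueError):
            MTSimParams(n_traces=0)
        with pytest.raises(ValueError):
            MTSimParams(n_traces=5, dynamicity=-0.1)


class TestConfocalStack:
    def test_flat_field(self):
        raw, truth, masks = simulate_confocal_stack(
            StackSimParams(perinuclear_enrichment=1.0, noise_sd=0.0)
        )
        tub = truth.channels["tubulin"]
        assert tub[masks["shell"]].mean() == pytest.approx(tub[masks["cytoplasm"]].mean())

    def test_enrichment_two_on_ground_truth_masks(self):
        raw, truth, masks = simulate_confocal_stack(
            StackSimParams(perinuclear_enrichment=2.0, noise_sd=0.0)
        )
        tub = raw.channels["tubulin"]  # identity gain: raw == true
        ratio = tub[masks["shell"]].mean() / tub[masks["cytoplasm"]].mean()
        assert ratio == pytest.approx(2.0, rel=1e-12)

    def test_gain_curve_recovered_from_calibration(self):
        coeffs = (10.0, 0.5, 0.001)
        xs = np.array([100.0, 500.0, 1000.0])
        ys = coeffs[0] + coeffs[1] * xs + coeffs[2] * xs**2
        curve = fit_gain_curve(np.column_stack([xs, ys]))
        assert curve.a0 == pytest.approx(10.0, rel=1e-9)
        assert curve.a1 == pytest.approx(0.5, rel=1e-9)
        assert curve.a2 == pytest.approx(0.001, rel=1e-9)

    def test_nonmonotonic_gain_rejected(self):
        with pytest.raises(ValueError):
            simulate_confocal_stack(StackSimParams(gain_coeffs=(0.0, -1.0, 0.0)))

    def test_masks_disjoint(self):
        _, _, masks = simulate_confocal_stack(StackSimParams())
        assert not np.any(masks["nuclear"] & masks["shell"])
        assert not np.any(masks["shell"] & masks["cytoplasm"])

    def test_determinism(self):
        p = StackSimParams(noise_sd=2.0, seed=11)
        a, _, _ = simulate_confocal_stack(p)
        b, _, _ = simulate_confocal_stack(p)
        np.testing.assert_array_equal(a.channels["tubulin"], b.channels["tubulin"])

    def test_nucleus_must_fit(self):
        with pytest.raises(ValueError, match="fit"):
            StackSimParams(shape=(32, 32, 32), voxel_size=(0.3, 0.3, 0.3), nucleus_radius=8.0)


class TestCohort:
    def test_no_censoring_all_events(self):
        table = simulate_cohort(50, censor_rate=0.0, seed=0)
        assert table["event"].sum() == 50

    def test_censoring_rate(self):
        table = simulate_cohort(2000, censor_rate=0.3, seed=1)
        assert table["event"].mean() == pytest.approx(0.7, abs=0.03)

    def test_low_arm_size(self):
        table = simulate_cohort(100, seed=2)
        low = table["expression"] < np.percentile(table["expression"], 25)
        assert abs(low.sum() - 25) <= 1

    def test_determinism(self):
        a = simulate_cohort(40, 2.0, 0.1, seed=3)
        b = simulate_cohort(40, 2.0, 0.1, seed=3)
        assert a.equals(b)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            simulate_cohort(4)
        with pytest.raises(ValueError):
            simulate_cohort(20, hazard_ratio_low_vs_high=0.0)


class TestIntensityTable:
    def test_exact_enriched_count(self):
        from cytomech.enrich import dep_filter, fold_enrichment

        table = simulate_intensity_table(417, 130, seed=0)
        deps = dep_filter(fold_enrichment(table, "auto"), threshold=2.0)
        assert len(deps) == 130
        assert set(deps) == set(table.loc[table["true_enriched"], "protein_id"])

    def test_all_labeled(self):
        table = simulate_intensity_table(50, 10, seed=1)
        assert table["category"].notna().all()

    def test_bounds(self):
        with pytest.raises(ValueError):
            simulate_intensity_table(10, 11)
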