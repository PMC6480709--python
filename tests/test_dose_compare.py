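"""DVH, percentage of agreement, gamma analysis and alpha/Delta."""

import numpy as np
import pytest

from dynaverify import (
    DVH,
    ComparisonReport,
    DoseGrid,
    GammaCriteria,
    StructureMask,
    compare,
    compute_dvh,
    gamma_pass_rate,
    gamma_values,
    percentage_of_agreement,
    read_rtdose,
    systematic_differences,
    write_rtdose,
)
from dynaverify.dose_compare import gamma_search_offsets, _interp_eval
from dynaverify.exceptions import (
    DoseComparisonError,
    UncertaintyRequiredError,
)


def _grid(values, spacing=(0.5, 0.5, 0.5), sigma=None):
    values = np.asarray(values, dtype=float)
    return DoseGrid(values, np.array(spacing), np.zeros(3), sigma=sigma)


def _full_mask(grid, name="roi"):
    return StructureMask(name, np.ones(grid.shape, dtype=bool), grid.spacing_cm)


class TestDVH:
    def test_uniform_dose_step_function(self):
        g = _grid(np.full((3, 3, 1), 2.0))
        dvh = compute_dvh(g, _full_mask(g), 1.0)
        assert dvh.volumes.tolist() == [100.0, 100.0, 100.0, 0.0]

    def test_two_voxel_enumeration(self):
        g = _grid(np.array([[[1.0, 3.0]]]))
        dvh = compute_dvh(g, _full_mask(g), 1.0)
        assert dvh.volumes.tolist() == [100.0, 100.0, 50.0, 50.0, 0.0]

    def test_empty_mask_errors(self):
        g = _grid(np.ones((2, 2, 2)))
        mask = StructureMask("empty", np.zeros((2, 2, 2), dtype=bool))
        with pytest.raises(DoseComparisonError):
            compute_dvh(g, mask, 1.0)

    def test_volumes_non_increasing_and_bounded(self, reference_dose, phantom):
        for mask in phantom.structure_masks().values():
            dvh = compute_dvh(reference_dose, mask, 0.01)
            assert dvh.volumes[0] == 100.0
            assert dvh.volumes[-1] == 0.0
            assert np.all(np.diff(dvh.volumes) <= 0)


class TestPercentageOfAgreement:
    def test_identical_dvhs_give_100(self):
        h = DVH(1.0, [100.0, 50.0, 10.0, 0.0])
        assert percentage_of_agreement(h, h) == 100.0

    def test_hand_worked_example(self):
        """delta_A = 10, A1 = 150, A2 = 140 -> PA = 100 (1 - 10/150)."""
        h1 = DVH(1.0, [100.0, 50.0, 0.0])
        h2 = DVH(1.0, [100.0, 40.0, 0.0])
        assert percentage_of_agreement(h1, h2) == pytest.approx(
            100.0 * (1.0 - 10.0 / 150.0), abs=1e-9)

    def test_empty_vs_any_gives_0(self):
        h1 = DVH(1.0, [100.0, 50.0, 0.0])
        h2 = DVH(1.0, [0.0, 0.0, 0.0])
        assert percentage_of_agreement(h1, h2) == pytest.approx(0.0)

    def test_both_empty_undefined(self):
        h = DVH(1.0, [0.0, 0.0])
        with pytest.raises(DoseComparisonError):
            percentage_of_agreement(h, h)

    def test_symmetry_and_range(self, rng):
        for _ in range(20):
            v1 = np.sort(rng.uniform(0, 100, 12))[::-1]
            v2 = np.sort(rng.uniform(0, 100, 8))[::-1]
            h1, h2 = DVH(0.5, v1), DVH(0.5, v2)
            pa12 = percentage_of_agreement(h1, h2)
            pa21 = percentage_of_agreement(h2, h1)
            assert pa12 == pytest.approx(pa21, abs=1e-12)
            assert 0.0 <= pa12 <= 100.0

    def test_zero_padding_of_shorter_histogram(self):
        h1 = DVH(1.0, [100.0, 60.0, 20.0, 0.0])
        h2 = DVH(1.0, [100.0, 60.0])
        # padding h2 with zeros: delta_A = 20, A1 = 180, A2 = 160
        assert percentage_of_agreement(h1, h2) == pytest.approx(
            100.0 * (1.0 - 20.0 / 180.0))

    def test_growing_binwise_gap_never_raises_pa(self):
        base = np.array([100.0, 80.0, 40.0, 0.0])
        pas = []
        for gap in (0.0, 5.0, 10.0, 20.0):
            other = base.copy()
            other[2] -= gap
            pas.append(percentage_of_agreement(DVH(1.0, base), DVH(1.0, other)))
        assert all(a >= b for a, b in zip(pas, pas[1:]))

    def test_mismatched_bin_width_rejected(self):
        with pytest.raises(DoseComparisonError):
            percentage_of_agreement(DVH(1.0, [100.0, 0.0]), DVH(0.5, [100.0, 0.0]))


def brute_force_gamma(reference, evaluated, mask, criteria, norm_dose=None):
    """Exhaustive gamma: per-voxel python loop over the full offset set."""
    dmax = float(np.max(reference.values)) if norm_dose is None else norm_dose
    dose_tol = criteria.dose_percent / 100.0 * dmax
    cutoff = criteria.low_dose_cutoff_percent / 100.0 * dmax
    offsets_cm, dist_mm = gamma_search_offsets(criteria)
    eligible = mask.voxels & (reference.values >= cutoff)
    out = []
    for idx in np.argwhere(eligible):
        pos = reference.origin_cm + idx * reference.spacing_cm
        ref_d = reference.values[tuple(idx)]
        ev = _interp_eval(evaluated, pos[None, :] + offsets_cm)
        g2 = ((ev - ref_d) / dose_tol) ** 2 + (dist_mm / criteria.dta_mm) ** 2
        out.append(np.sqrt(g2.min()))
    return np.array(out)


# coarse search keeps the exhaustive oracle cheap; the search logic under
# test is identical at any step/radius
_FAST = dict(search_step_fraction=1.0 / 3.0, search_radius_factor=1.5)


class TestGamma:
    def test_identical_grids_pass_everywhere(self, reference_dose, phantom):
        gpr = gamma_pass_rate(reference_dose, reference_dose,
                              phantom.structure_masks()["body"],
                              GammaCriteria(2, 2))
        assert gpr == 100.0

    def test_one_percent_scaling_passes_2pct_criterion(self, rng):
        vals = rng.uniform(0.2, 1.0, (6, 6, 6))
        ref = _grid(vals)
        ev = _grid(vals * 1.01)
        gpr = gamma_pass_rate(ref, ev, _full_mask(ref), GammaCriteria(2, 1, **_FAST))
        assert gpr == 100.0

    def test_single_bumped_voxel_fails_alone(self):
        """One voxel pushed 5% of max with a 3%/tiny-DTA criterion: exactly
        24 of 25 eligible voxels pass."""
        vals = np.full((5, 5, 1), 1.0)
        ref = _grid(vals)
        bumped = vals.copy()
        bumped[2, 2, 0] += 0.05
        crit = GammaCriteria(3, 0.0001, low_dose_cutoff_percent=0,
                             search_step_fraction=1.0, search_radius_factor=0.5)
        gpr = gamma_pass_rate(ref, _grid(bumped), _full_mask(ref), crit)
        assert gpr == pytest.approx(100.0 * 24 / 25)

    def test_optimized_equals_brute_force(self, rng):
        """Shell search with early termination must match exhaustive
        enumeration exactly, including on disagreeing grid pairs."""
        crit = GammaCriteria(2, 1, low_dose_cutoff_percent=10, **_FAST)
        for _ in range(25):
            shape = tuple(rng.integers(3, 8, 3))
            ref = _grid(rng.uniform(0, 1, shape), spacing=(0.25, 0.25, 0.25))
            ev = _grid(np.clip(ref.values + rng.normal(0, 0.05, shape), 0, None),
                       spacing=(0.25, 0.25, 0.25))
            mask = _full_mask(ref)
            fast = gamma_values(ref, ev, mask, crit)
            brute = brute_force_gamma(ref, ev, mask, crit)
            assert np.allclose(fast, brute, rtol=0, atol=1e-12)

    def test_gpr_non_decreasing_when_criteria_loosened(self, rng):
        vals = rng.uniform(0, 1, (7, 7, 5))
        ref = _grid(vals)
        ev = _grid(np.clip(vals + rng.normal(0, 0.03, vals.shape), 0, None))
        mask = _full_mask(ref)
        gprs = [
            gamma_pass_rate(ref, ev, mask, GammaCriteria(d, r, **_FAST))
            for d, r in [(1, 1), (2, 1), (2, 2), (3, 3)]
        ]
        assert all(a <= b for a, b in zip(gprs, gprs[1:]))

    def test_no_voxel_above_cutoff_errors(self):
        ref = _grid(np.full((3, 3, 3), 1.0))
        ev = _grid(np.full((3, 3, 3), 1.0))
        mask = _full_mask(ref)
        crit = GammaCriteria(2, 2, low_dose_cutoff_percent=10)
        with pytest.raises(DoseComparisonError):
            gamma_pass_rate(ref, ev, mask, crit, norm_dose=1000.0)


class TestSystematicDifferences:
    def test_identical_grids_zero_alpha(self):
        vals = np.full((4, 4, 4), 1.0)
        g = _grid(vals, sigma=np.zeros_like(vals))
        sd = systematic_differences(g, g, _full_mask(g))
        assert all(alpha == 0.0 for alpha, delta in sd.pairs if delta > 0)

    def test_constant_offset_step_response(self):
        """A 2%-of-max offset with zero noise: alpha = 100 up to Delta = 2,
        0 beyond."""
        vals = np.full((4, 4, 4), 1.0)
        ref = _grid(vals, sigma=np.zeros_like(vals))
        ev = _grid(vals + 0.02, sigma=np.zeros_like(vals))
        sd = systematic_differences(ref, ev, _full_mask(ref),
                                    delta_grid_percent=(1.0, 1.5, 2.0, 2.5, 3.0))
        assert sd.alpha_at(1.0) == 100.0
        assert sd.alpha_at(2.0) == 100.0
        assert sd.alpha_at(2.5) == 0.0
        assert sd.alpha_at(3.0) == 0.0

    def test_noise_only_pair_suppressed(self, rng):
        """Independent noise matching the declared sigma is absorbed by the
        quadrature subtraction: alpha(1%) stays small."""
        base = np.full((12, 12, 12), 1.0)
        sigma = np.full_like(base, 0.004)
        ref = _grid(np.clip(base + rng.normal(0, 0.004, base.shape), 0, None),
                    sigma=sigma)
        ev = _grid(np.clip(base + rng.normal(0, 0.004, base.shape), 0, None),
                   sigma=sigma)
        sd = systematic_differences(ref, ev, _full_mask(ref),
                                    delta_grid_percent=(1.0,))
        assert sd.alpha_at(1.0) < 5.0

    def test_alpha_non_increasing_in_delta(self, rng):
        vals = rng.uniform(0.5, 1.0, (6, 6, 6))
        sigma = np.full_like(vals, 0.005)
        ref = _grid(vals, sigma=sigma)
        ev = _grid(vals + rng.normal(0, 0.02, vals.shape).clip(-0.4, 0.4),
                   sigma=sigma)
        sd = systematic_differences(ref, ev, _full_mask(ref))
        alphas = [a for a, _ in sd.pairs]
        assert all(x >= y for x, y in zip(alphas, alphas[1:]))

    def test_missing_sigma_rejected(self):
        g = _grid(np.ones((3, 3, 3)))
        with pytest.raises(UncertaintyRequiredError):
            systematic_differences(g, g, _full_mask(g))


class TestReportAndIO:
    def test_identical_inputs_all_perfect(self, reference_dose, phantom):
        report = compare(reference_dose, reference_dose, phantom.structure_masks())
        for entry in report.structures.values():
            assert entry["pa"] == 100.0
            assert all(g == 100.0 for g in entry["gpr"].values())

    def test_report_json_round_trip(self, reference_dose, phantom):
        report = compare(reference_dose, reference_dose, phantom.structure_masks())
        back = ComparisonReport.from_json(report.to_json())
        assert back.to_dict() == report.to_dict()

    def test_per_structure_pa_matches_direct_call(self, reference_dose, phantom):
        masks = phantom.structure_masks()
        dmax = float(reference_dose.values[masks["body"].voxels].max())
        report = compare(reference_dose, reference_dose, masks)
        dvh = compute_dvh(reference_dose, masks["ptv"], dmax / 1000.0)
        assert report.structures["ptv"]["pa"] == percentage_of_agreement(dvh, dvh)

    def test_dose_grid_npz_round_trip(self, tmp_path, reference_dose):
        path = tmp_path / "dose.npz"
        reference_dose.save_npz(path)
        back = DoseGrid.load_npz(path)
        assert np.array_equal(back.values, reference_dose.values)
        assert back.congruent_with(reference_dose)

    def test_rtdose_round_trip(self, tmp_path, reference_dose):
        path = tmp_path / "dose.dcm"
        write_rtdose(reference_dose, path)
        back = read_rtdose(path)
        assert back.congruent_with(reference_dose)
        scale = reference_dose.values.max() / (2**32 - 1)
        assert np.allclose(back.values, reference_dose.values, atol=2 * scale)
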