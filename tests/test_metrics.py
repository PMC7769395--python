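"""DVH metrics and quality indices against brute-force voxel oracles."""

import numpy as np
import pytest

from dosenoise import (
    DoseGrid,
    StructureMask,
    StructureError,
    UndefinedIndexError,
    VolumeError,
    cumulative_dvh,
    dose_at_absolute_volume,
    dose_at_relative_volume,
    gradient_index,
    mean_dose,
    paddick_ci,
)

# ---------------------------------------------------------------------------
# independent brute-force oracles (straight re-statements of the definitions)
# ---------------------------------------------------------------------------


def oracle_dose_at_relative_volume(doses, v_pct):
    """Largest D with >= v_pct% of voxels at or above D, by direct scan."""
    best = None
    for d in sorted(set(doses), reverse=True):
        frac = 100.0 * np.sum(doses >= d) / len(doses)
        if frac >= v_pct:
            best = d if best is None else max(best, d)
    return best


def oracle_dose_at_absolute_volume(doses, vox_cc, v_cc):
    desc = sorted(doses, reverse=True)
    cum = 0.0
    for d in desc:
        cum += vox_cc
        if cum >= v_cc - 1e-12:
            return d
    raise AssertionError("volume exceeds region")


def oracle_paddick(doses, in_tv, rx):
    tv = int(np.sum(in_tv))
    tvpiv = int(np.sum((doses >= rx) & in_tv))
    vri = int(np.sum(doses >= rx))
    if tvpiv == 0:
        return 0.0
    return tvpiv**2 / (tv * vri)


def oracle_gi(doses, rx):
    return np.sum(doses >= rx / 2) / np.sum(doses >= rx)


def _random_case(rng):
    shape = tuple(rng.integers(2, 9, size=3))
    values = rng.uniform(0, 60, size=shape)
    # duplicate some values to exercise ties
    if values.size >= 8:
        flat = values.ravel()
        idx = rng.integers(0, flat.size, size=flat.size // 4)
        flat[idx] = rng.choice(flat, size=idx.size)
    grid = DoseGrid(values=values, spacing_cm=float(rng.choice([0.1, 0.2])))
    mask = rng.random(shape) < 0.6
    if not mask.any():
        mask.flat[0] = True
    return grid, StructureMask("tv", mask, grid.spacing_cm)


class TestDoseAtRelativeVolume:
    def test_uniform(self):
        grid = DoseGrid(values=np.full((3, 3, 3), 7.0), spacing_cm=0.1)
        mask = StructureMask("m", np.ones((3, 3, 3), bool), 0.1)
        for v in (1, 50, 98, 100):
            assert dose_at_relative_volume(grid, mask, v) == 7.0

    def test_sorted_list_example(self):
        values = np.arange(1.0, 11.0).reshape(1, 2, 5)
        grid = DoseGrid(values=values, spacing_cm=0.1)
        mask = StructureMask("m", np.ones((1, 2, 5), bool), 0.1)
        assert dose_at_relative_volume(grid, mask, 20.0) == 9.0
        assert dose_at_relative_volume(grid, mask, 100.0) == 1.0

    def test_monotone_in_volume(self, rng):
        grid, mask = _random_case(rng)
        vols = np.linspace(1, 100, 25)
        doses = [dose_at_relative_volume(grid, mask, v) for v in vols]
        assert np.all(np.diff(doses) <= 0)

    def test_against_oracle(self, rng):
        for _ in range(200):
            grid, mask = _random_case(rng)
            v = float(rng.uniform(1, 100))
            got = dose_at_relative_volume(grid, mask, v)
            assert got == oracle_dose_at_relative_volume(
                grid.values[mask.mask], v
            )

    def test_empty_mask_rejected(self):
        grid = DoseGrid(values=np.ones((2, 2, 2)), spacing_cm=0.1)
        with pytest.raises(StructureError):
            dose_at_relative_volume(
                grid, StructureMask("m", np.zeros((2, 2, 2), bool), 0.1), 50
            )


class TestDoseAtAbsoluteVolume:
    def test_one_voxel_volume_is_max(self, random_grid):
        assert (
            dose_at_absolute_volume(random_grid, None,
                                    random_grid.voxel_volume_cc)
            == random_grid.max_dose
        )

    def test_near_max_is_35th_highest_at_1mm(self, rng):
        values = rng.uniform(0, 50, size=(10, 10, 10))
        grid = DoseGrid(values=values, spacing_cm=0.1)
        expected = np.sort(values.ravel())[::-1][34]
        assert dose_at_absolute_volume(grid, None, 0.035) == expected

    def test_against_oracle(self, rng):
        for _ in range(200):
            grid, mask = _random_case(rng)
            vol = mask.voxel_count * grid.voxel_volume_cc
            v_cc = float(rng.uniform(0.2, 1.0)) * vol
            got = dose_at_absolute_volume(grid, mask, v_cc)
            assert got == oracle_dose_at_absolute_volume(
                grid.values[mask.mask], grid.voxel_volume_cc, v_cc
            )

    def test_volume_beyond_region_rejected(self, random_grid):
        with pytest.raises(VolumeError):
            dose_at_absolute_volume(
                random_grid, None,
                random_grid.values.size * random_grid.voxel_volume_cc + 1.0,
            )


class TestMeanDose:
    def test_examples(self):
        grid = DoseGrid(values=np.array([[[1.0, 3.0]]]), spacing_cm=0.1)
        mask = StructureMask("m", np.ones((1, 1, 2), bool), 0.1)
        assert mean_dose(grid, mask) == 2.0


class TestPaddickCI:
    def test_perfect_conformity(self):
        values = np.zeros((4, 4, 4))
        values[1:3, 1:3, 1:3] = 20.0
        grid = DoseGrid(values=values, spacing_cm=0.1)
        tv = StructureMask("tv", values >= 20.0, 0.1)
        assert paddick_ci(grid, tv, 20.0) == 1.0

    def test_no_coverage_is_zero(self):
        grid = DoseGrid(values=np.ones((3, 3, 3)), spacing_cm=0.1)
        tv = StructureMask("tv", np.ones((3, 3, 3), bool), 0.1)
        assert paddick_ci(grid, tv, 50.0) == 0.0

    def test_toy_counts(self):
        # TVPIV = 8, TV = 10, VRI = 10 -> 64/100
        values = np.zeros((1, 1, 16))
        tv = np.zeros((1, 1, 16), bool)
        tv[0, 0, :10] = True
        values[0, 0, :8] = 30.0     # hot target voxels
        values[0, 0, 14:] = 30.0    # hot voxels outside target
        grid = DoseGrid(values=values, spacing_cm=0.1)
        assert paddick_ci(grid, StructureMask("tv", tv, 0.1), 30.0) == \
            pytest.approx(0.64)

    def test_bounded_by_one_and_matches_oracle(self, rng):
        for _ in range(200):
            grid, tv = _random_case(rng)
            rx = float(rng.uniform(5, 55))
            got = paddick_ci(grid, tv, rx)
            assert 0.0 <= got <= 1.0
            assert got == pytest.approx(
                oracle_paddick(grid.values, tv.mask, rx)
            )

    def test_scaling_invariance(self, rng):
        grid, tv = _random_case(rng)
        rx = 25.0
        scaled = grid.with_values(grid.values * 2.0)
        assert paddick_ci(grid, tv, rx) == paddick_ci(scaled, tv, 2 * rx)


class TestGradientIndex:
    def test_uniform_at_rx(self):
        grid = DoseGrid(values=np.full((3, 3, 3), 10.0), spacing_cm=0.1)
        assert gradient_index(grid, 10.0) == 1.0

    def test_toy_counts(self):
        values = np.zeros((1, 1, 50))
        values[0, 0, :10] = 20.0    # VRI = 10 voxels
        values[0, 0, 10:35] = 11.0  # + 25 more at half-dose -> VR50 = 35
        grid = DoseGrid(values=values, spacing_cm=0.1)
        assert gradient_index(grid, 20.0) == pytest.approx(3.5)

    def test_at_least_one_and_matches_oracle(self, rng):
        for _ in range(200):
            grid, _ = _random_case(rng)
            rx = float(np.quantile(grid.values, rng.uniform(0.2, 0.9)))
            if rx <= 0 or not (grid.values >= rx).any():
                continue
            got = gradient_index(grid, rx)
            assert got >= 1.0
            assert got == pytest.approx(oracle_gi(grid.values, rx))

    def test_undefined_when_no_voxel_reaches_rx(self):
        grid = DoseGrid(values=np.ones((2, 2, 2)), spacing_cm=0.1)
        with pytest.raises(UndefinedIndexError):
            gradient_index(grid, 5.0)


class TestCumulativeDVH:
    def test_uniform_step_function(self):
        grid = DoseGrid(values=np.full((3, 3, 3), 10.0), spacing_cm=0.1)
        mask = StructureMask("m", np.ones((3, 3, 3), bool), 0.1)
        curve = cumulative_dvh(grid, mask, bin_width_gy=1.0)
        assert curve.rel_volume[0] == 100.0
        assert np.all(curve.rel_volume[curve.dose_axis <= 10.0] == 100.0)
        assert np.all(curve.rel_volume[curve.dose_axis > 10.0] == 0.0)

    def test_enumerated_quarters(self):
        values = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        grid = DoseGrid(values=values, spacing_cm=0.1)
        mask = StructureMask("m", np.ones((1, 2, 2), bool), 0.1)
        curve = cumulative_dvh(grid, mask, bin_width_gy=0.5)
        at = dict(zip(curve.dose_axis, curve.rel_volume))
        assert at[2.5] == 50.0
        assert at[0.5] == 100.0
        assert at[4.5] == 0.0

    def test_monotone_non_increasing(self, rng):
        grid, mask = _random_case(rng)
        curve = cumulative_dvh(grid, mask, bin_width_gy=0.7)
        assert np.all(np.diff(curve.rel_volume) <= 0)
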