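"""Speed-modulation function: fit, assembly, sweep and diagnostics."""

import numpy as np
import pytest

from reflexgait.controller import ParameterVector
from reflexgait.key_params import KeySelection
from reflexgait.smf import (
    MonotonicityReport,
    SMFModel,
    SweepResult,
    assemble,
    default_grid,
    fit_smf,
    monotonicity_report,
    offline_sweep,
    online_target_bounds,
)
from reflexgait.speed_opt import SpeedDataset
from reflexgait.toybench import SyntheticDatasetSpec, gen_param_speed_dataset


TRUE_KEYS = (2, 9, 33, 50, 68)
TRUE_COEFFS = np.array(
    [
        [0.5, -0.2, 0.0, 0.1],
        [0.0, 1.0, -0.3, 0.0],
        [1.2, 0.0, 0.2, -0.05],
        [-0.4, 0.3, 0.0, 0.02],
        [0.1, 0.0, 0.0, 0.2],
    ]
)


@pytest.fixture(scope="module")
def cubic_dataset():
    return gen_param_speed_dataset(
        SyntheticDatasetSpec(
            true_keys=TRUE_KEYS, coeffs=TRUE_COEFFS, noise_sd=0.0, n_v=80, seed=21
        )
    )


@pytest.fixture(scope="module")
def keys():
    return KeySelection(n_key=5, indices=TRUE_KEYS, kinds=("kL",) * 5)


@pytest.fixture(scope="module")
def p_init(std_matrix):
    rng = np.random.default_rng(9)
    return ParameterVector.decode(std_matrix, rng.normal(size=71))


class TestFit:
    def test_noiseless_cubic_recovered_to_1e8(self, cubic_dataset, keys, p_init):
        model = fit_smf(cubic_dataset, keys, degree=3, p_init=p_init)
        assert np.abs(model.beta - TRUE_COEFFS).max() < 1e-8

    def test_noiseless_linear_recovered_exactly(self, keys, p_init):
        coeffs = np.zeros((5, 4))
        coeffs[:, 0] = np.arange(5) * 0.1
        coeffs[:, 1] = 1.0 + np.arange(5) * 0.2
        ds = gen_param_speed_dataset(
            SyntheticDatasetSpec(
                true_keys=TRUE_KEYS, coeffs=coeffs, noise_sd=0.0, n_v=40, seed=22
            )
        )
        model = fit_smf(ds, keys, degree=1, p_init=p_init)
        assert np.abs(model.beta - coeffs).max() < 1e-9

    def test_coefficients_above_degree_are_zero(self, cubic_dataset, keys, p_init):
        model = fit_smf(cubic_dataset, keys, degree=2, p_init=p_init)
        assert np.all(model.beta[:, 3] == 0.0)

    def test_degenerate_design_rejected(self, keys, p_init):
        ds = SpeedDataset(np.zeros((10, 71)), np.full(10, 1.3))
        with pytest.raises(ValueError, match="degenerate"):
            fit_smf(ds, keys, degree=1, p_init=p_init)

    def test_too_few_records_rejected(self, keys, p_init):
        ds = SpeedDataset(np.zeros((3, 71)), np.array([1.0, 1.1, 1.2]))
        with pytest.raises(ValueError, match="need more than"):
            fit_smf(ds, keys, degree=3, p_init=p_init)


class TestAssemble:
    def test_non_key_entries_equal_p_init_exactly(self, cubic_dataset, keys, p_init):
        model = fit_smf(cubic_dataset, keys, degree=3, p_init=p_init)
        non_keys = [i for i in range(71) if i not in TRUE_KEYS]
        for v in (0.5, 1.1, 3.4):
            out = assemble(model, v).encode()
            assert np.array_equal(out[non_keys], p_init.encode()[non_keys])

    def test_dataset_records_reproduced_at_their_speeds(self, cubic_dataset, keys, p_init):
        model = fit_smf(cubic_dataset, keys, degree=3, p_init=p_init)
        for i in range(0, len(cubic_dataset), 13):
            v = cubic_dataset.v_act[i]
            out = assemble(model, float(v)).encode()
            assert np.allclose(
                out[list(TRUE_KEYS)],
                cubic_dataset.params[i, list(TRUE_KEYS)],
                atol=1e-8,
            )

    def test_continuity_in_target_speed(self, cubic_dataset, keys, p_init):
        model = fit_smf(cubic_dataset, keys, degree=3, p_init=p_init)
        a = assemble(model, 1.0).encode()
        b = assemble(model, 1.0 + 1e-6).encode()
        assert np.abs(a - b).max() < 1e-4  # O(1e-6) scaled by coefficients

    def test_pass_through_of_changed_non_key_entry(self, cubic_dataset, keys, p_init):
        model = fit_smf(cubic_dataset, keys, degree=3, p_init=p_init)
        modified = p_init.encode()
        non_key = next(i for i in range(71) if i not in TRUE_KEYS)
        modified[non_key] += 0.7
        model2 = SMFModel(
            degree=model.degree,
            keys=model.keys,
            beta=model.beta,
            p_init=ParameterVector.decode(p_init.matrix, modified),
        )
        out = assemble(model2, 2.0).encode()
        assert out[non_key] == modified[non_key]


class TestSweep:
    def test_default_grid_has_121_points(self):
        grid = default_grid()
        assert len(grid) == 121
        assert grid[0] == 0.5 and grid[-1] == 3.5
        assert np.allclose(np.diff(grid), 0.025)

    def test_toy_sweep_records_stability_and_speed(self, toy, toy_cfg):
        plant, p0 = toy
        # constant modulation: every target assembles the stable baseline
        keys = KeySelection(n_key=1, indices=(4,), kinds=("kF",))
        beta = np.zeros((1, 4))
        beta[0, 0] = p0.encode()[4]
        model = SMFModel(degree=1, keys=keys, beta=beta, p_init=p0)
        sweep = offline_sweep(plant, model, np.array([1.0, 1.5, 2.0]), toy_cfg)
        assert sweep.stable.all()
        assert np.all(np.isfinite(sweep.v_act))
        assert all(g == "run" for g in sweep.gait)
        assert model.stable_range == (1.0, 2.0)

    def test_sweep_determinism(self, toy, toy_cfg):
        plant, p0 = toy
        keys = KeySelection(n_key=1, indices=(4,), kinds=("kF",))
        beta = np.zeros((1, 4))
        beta[0, 0] = p0.encode()[4]
        model = SMFModel(degree=1, keys=keys, beta=beta, p_init=p0)
        grid = np.array([1.4, 1.6])
        a = offline_sweep(plant, model, grid, toy_cfg)
        b = offline_sweep(plant, model, grid, toy_cfg)
        assert np.array_equal(a.v_act, b.v_act)

    def test_grid_must_increase(self):
        with pytest.raises(ValueError):
            SweepResult(
                v_tgt=np.array([1.0, 1.0]),
                stable=np.array([True, True]),
                v_act=np.array([1.0, 1.0]),
                gait=["run", "run"],
            )


class TestMonotonicity:
    def _sweep(self, v_tgt, v_act):
        v_tgt = np.asarray(v_tgt, dtype=float)
        v_act = np.asarray(v_act, dtype=float)
        return SweepResult(
            v_tgt=v_tgt,
            stable=np.ones(len(v_tgt), dtype=bool),
            v_act=v_act,
            gait=["run"] * len(v_tgt),
        )

    def test_strictly_increasing_has_no_violations(self):
        rep = monotonicity_report(self._sweep([1, 2, 3, 4], [1.0, 1.2, 1.5, 1.9]))
        assert rep.n_violations == 0
        assert rep.longest_monotone_run == 4

    def test_single_inversion_reported_once(self):
        rep = monotonicity_report(self._sweep([1, 2, 3, 4], [1.0, 1.5, 1.4, 1.9]))
        assert rep.violations == (1,)

    def test_identity_relation_has_zero_deviation(self):
        rep = monotonicity_report(self._sweep([1.0, 1.5, 2.0], [1.0, 1.5, 2.0]))
        assert rep.max_identity_deviation == 0.0
        assert rep.rms_identity_deviation == 0.0

    def test_online_bounds_exclude_extreme_targets(self):
        sweep = self._sweep(
            [1.0, 1.1, 1.2, 1.3, 1.4], [0.9, 1.0, 1.15, 1.3, 1.45]
        )
        lo, hi = online_target_bounds(sweep)
        assert lo == 1.1 and hi == 1.3
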