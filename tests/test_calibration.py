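import numpy as np
import pandas as pd
import pytest

from dcvax import datasets as dsets
from dcvax.calibration import (
    CalibrationPlan,
    CalibrationStage,
    calibrate,
    cost_function,
    default_plan,
    global_search,
    lhs_sample,
    local_refine,
    model_cost,
    pattern_search,
)


def _toy_dataset(values, sds):
    f = pd.DataFrame({
        "observable": ["obs"] * len(values), "arm": ["x"] * len(values),
        "time_h": np.arange(1.0, len(values) + 1.0),
        "value": values, "sd": sds, "n": [3] * len(values),
    })
    return dsets.Dataset(kind="cytokine", frame=f, max_normalized=False)


# ---------------------------------------------------------------------------
# cost function
# ---------------------------------------------------------------------------

def test_cost_zero_iff_exact_match():
    ds = _toy_dataset([2.0, 4.0], [np.nan, np.nan])
    assert cost_function(ds, np.array([2.0, 4.0])) == 0.0
    assert cost_function(ds, np.array([2.0, 4.1])) > 0.0


def test_cost_hand_value():
    """y = {2 (sd 1), 4 (sd 2)}, sim = {2, 2}, max = 4 -> (2/(4*2))^2."""
    ds = _toy_dataset([2.0, 4.0], [1.0, 2.0])
    assert cost_function(ds, np.array([2.0, 2.0])) == pytest.approx(0.0625)


def test_cost_scales_inversely_with_sd_squared():
    pred = np.array([2.0, 2.0])
    phi1 = cost_function(_toy_dataset([2.0, 4.0], [1.0, 2.0]), pred)
    phi3 = cost_function(_toy_dataset([2.0, 4.0], [3.0, 6.0]), pred)
    assert phi3 == pytest.approx(phi1 / 9.0)


def test_cost_invariant_to_row_order(noiseless_datasets, ref_params):
    from dcvax.calibration import predict_dataset

    ds = noiseless_datasets["cytokine"]
    perm = np.random.default_rng(0).permutation(len(ds.frame))
    shuffled = dsets.Dataset(kind=ds.kind,
                             frame=ds.frame.iloc[perm].reset_index(drop=True),
                             max_normalized=ds.max_normalized)
    p_mod = ref_params.with_overrides({"k_deg_mIL8": 0.3})
    phi_a = cost_function(ds, predict_dataset(ds, p_mod))
    phi_b = cost_function(shuffled, predict_dataset(shuffled, p_mod))
    assert phi_a == pytest.approx(phi_b, rel=1e-12)


def test_cost_rejects_zero_maximum():
    ds = _toy_dataset([0.0, 0.0], [np.nan, np.nan])
    with pytest.raises(ZeroDivisionError):
        cost_function(ds, np.array([0.0, 0.0]))


def test_noiseless_closure_over_all_kinds(noiseless_datasets, ref_params):
    """Simulating at the generating parameters reproduces noiseless data:
    the calibration loop closes with cost ~ 0."""
    phi = model_cost(list(noiseless_datasets.values()), ref_params)
    assert phi < 1e-9


# ---------------------------------------------------------------------------
# Latin hypercube sampling
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n,d", [(4, 2), (50, 5)])
def test_lhs_stratification_exact(n, d):
    bounds = [(0.0, 1.0)] * d
    x = lhs_sample(n, bounds, seed=3)
    for j in range(d):
        counts = np.histogram(x[:, j], bins=n, range=(0.0, 1.0))[0]
        assert np.all(counts == 1)


def test_lhs_reproducible_and_scaled():
    bounds = [(10.0, 20.0), (-1.0, 1.0)]
    a = lhs_sample(100, bounds, seed=5)
    b = lhs_sample(100, bounds, seed=5)
    np.testing.assert_array_equal(a, b)
    assert a[:, 0].min() >= 10.0 and a[:, 0].max() <= 20.0
    # per-dimension mean near the midpoint
    assert abs(a[:, 0].mean() - 15.0) / 5.0 < 2.0 / np.sqrt(100)


def test_lhs_rejects_bad_bounds():
    with pytest.raises(ValueError):
        lhs_sample(10, [(1.0, 0.0)])
    with pytest.raises(ValueError):
        lhs_sample(0, [(0.0, 1.0)])


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

def test_pattern_search_solves_sphere():
    x, fx, _ = pattern_search(lambda x: float(np.sum(x * x)),
                              np.array([0.7, -0.6]), [(-1, 1), (-1, 1)],
                              budget=4000)
    assert np.all(np.abs(x) < 1e-4)


def test_global_search_rosenbrock_best_of_50():
    rng = np.random.default_rng(0)
    rb = lambda x: float((1 - x[0]) ** 2 + 100 * (x[1] - x[0] ** 2) ** 2)
    sols = global_search(rb, rng.uniform(-2, 2, (50, 2)), [(-2, 2)] * 2,
                         budget_per_start=20000)
    assert np.max(np.abs(sols[0][0] - 1.0)) < 2e-3


def test_global_search_survives_nan_objective():
    def sometimes_nan(x):
        return np.nan if x[0] < 0 else float(x[0] ** 2)

    starts = np.array([[-0.5], [0.5]])
    sols = global_search(sometimes_nan, starts, [(-1, 1)], budget_per_start=200)
    assert np.isfinite(sols[0][1])
    assert np.isinf(sols[-1][1])


def test_local_refine_exact_on_quadratic():
    f = lambda x: float(np.sum((x - 0.3) ** 2))
    x0 = np.array([0.0, 0.9])
    out = local_refine(f, [(x0, f(x0))], [(-1, 1)] * 2)
    assert out[0][1] < 1e-8
    np.testing.assert_allclose(out[0][0], 0.3, atol=1e-4)


def test_local_refine_never_worsens():
    f = lambda x: float(np.cos(20 * x[0]) + x[0] ** 2)
    for s in np.linspace(-1, 1, 7):
        x0 = np.array([s])
        out = local_refine(f, [(x0, f(x0))], [(-1, 1)])
        assert out[0][1] <= f(x0) + 1e-12


def test_il8_parameters_recovered_from_noiseless_data(noiseless_datasets,
                                                      ref_params):
    """Local refinement recovers the IL-8 chain parameters to << 10%
    relative error from noiseless synthetic cytokine data."""
    ds = noiseless_datasets["cytokine"]
    free = ["k_transc1_mIL8", "k_transc2_mIL8", "k_deg_mIL8"]
    truth = np.array([ref_params[n] for n in free])

    def obj(x):
        trial = ref_params.with_overrides(dict(zip(free, 10.0 ** x)))
        return model_cost([ds], trial)

    x0 = np.log10(truth) + np.array([0.3, -0.3, 0.2])
    out = local_refine(obj, [(x0, obj(x0))], [(-4.0, 2.0)] * 3)
    rel = np.abs(10.0 ** out[0][0] - truth) / truth
    assert np.all(rel < 0.10)


# ---------------------------------------------------------------------------
# staged calibration
# ---------------------------------------------------------------------------

def test_default_plan_structure():
    plan = default_plan()
    assert [s.name for s in plan.stages] == ["biodistribution", "nfkb",
                                             "cytokine", "tcell"]
    assert plan.stages[-1].free == ("K_4",)
    with pytest.raises(ValueError):
        CalibrationPlan(stages=[
            CalibrationStage("a", ("nfkb",), ("N_tot",)),
            CalibrationStage("b", ("cytokine",), ("N_tot",)),
        ])


def test_stage1_noiseless_self_consistency(noiseless_datasets, ref_params):
    """On noiseless data the hybrid search reaches cost < 1e-6 and never
    ends above its best LHS start."""
    plan = CalibrationPlan(stages=[default_plan().stages[0]])
    data = {"biodistribution": noiseless_datasets["biodistribution"]}
    res = calibrate(plan, data, ref_params, seed=3, n_starts=12,
                    top_global=12, budget_per_start=200)
    stage = res["biodistribution"]
    assert stage.best[1] < 1e-6
    start_costs = [c for _, c in stage.solutions]
    assert stage.best[1] <= min(start_costs)
    truth = np.array([ref_params[n] for n in stage.free_names])
    rel = np.abs(stage.best_values(1)[0] - truth) / truth
    assert np.all(rel < 0.10)


def test_calibration_reproducible_under_seed(noiseless_datasets, ref_params):
    plan = CalibrationPlan(stages=[default_plan().stages[0]])
    data = {"biodistribution": noiseless_datasets["biodistribution"]}
    kw = dict(seed=4, n_starts=6, top_global=6, budget_per_start=80)
    a = calibrate(plan, data, ref_params, **kw)["biodistribution"]
    b = calibrate(plan, data, ref_params, **kw)["biodistribution"]
    np.testing.assert_array_equal(a.best[0], b.best[0])
    assert a.best[1] == b.best[1]


def test_missing_dataset_raises_with_checkpoint(ref_params):
    from dcvax.calibration import CalibrationError

    with pytest.raises(CalibrationError) as err:
        calibrate(default_plan(), {}, ref_params, n_starts=2,
                  budget_per_start=10)
    assert err.value.completed == {}
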