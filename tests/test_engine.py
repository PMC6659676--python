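"""Update semantics, trajectories, ensembles, and the steady-state oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from costimnet import (
    Condition,
    ModelDefinition,
    Perturbation,
    SimulationSettings,
    UpdateRule,
    analytic_fixed_point,
    apply_condition,
    convergence_fraction,
    enumerate_fixed_points,
    initial_state,
    is_fixed_point,
    random_initial_state,
    run_ensemble,
    simulate,
    step,
)

# Steady states of the bundled model, derived by hand from the closed-form
# rules (topological evaluation on paper) and frozen here; the engine and
# both oracles must reproduce them.
EXPECTED_FIXED_POINTS = {
    "none": {"I": 0, "Ox": 0, "Tr1": 0, "Tr2": 0, "Tr5": 0, "Nk": 0,
             "PKB": 0, "ERK": 0, "JNK": 1, "Bim": 2, "S": 0, "C": 0},
    "monoI": {"I": 2, "Ox": 0, "Tr1": 2, "Tr2": 2, "Tr5": 0, "Nk": 1,
              "PKB": 1, "ERK": 2, "JNK": 2, "Bim": 1, "S": 1, "C": 1},
    "monoOx": {"I": 0, "Ox": 2, "Tr1": 0, "Tr2": 0, "Tr5": 2, "Nk": 1,
               "PKB": 1, "ERK": 0, "JNK": 0, "Bim": 0, "S": 1, "C": 1},
    "dual": {"I": 2, "Ox": 2, "Tr1": 2, "Tr2": 2, "Tr5": 2, "Nk": 2,
             "PKB": 2, "ERK": 2, "JNK": 1, "Bim": 0, "S": 2, "C": 2},
}

SCREEN_PERTURBATIONS = [()] + [
    (Perturbation(sp, level),)
    for sp in ("ERK", "PKB", "JNK", "Nk")
    for level in (0, 2)
]


def toy_model(rule_fns):
    """Small model over inputs I, Ox and free species X, Y for engine tests."""
    species = ("I", "Ox") + tuple(rule_fns)
    rules = {
        name: UpdateRule.from_function(name, parents, fn)
        for name, (parents, fn) in rule_fns.items()
    }
    return ModelDefinition(species=species, inputs=("I", "Ox"), rules=rules)


# ---------------------------------------------------------------------------
# Settings and initial state
# ---------------------------------------------------------------------------

def test_settings_bounds():
    with pytest.raises(ValueError):
        SimulationSettings(p=0.0)
    with pytest.raises(ValueError):
        SimulationSettings(p=1.5)
    with pytest.raises(ValueError):
        SimulationSettings(horizon=300, max_steps=200)
    with pytest.raises(ValueError):
        SimulationSettings(scheme="parallel")


def test_initial_state_is_clamps_plus_zeros(model):
    cmodel = apply_condition(
        model, Condition.from_treatment("dual", (Perturbation("Nk", 0),))
    )
    state = initial_state(cmodel)
    assert state["I"] == state["Ox"] == 2
    assert state["Nk"] == 0
    assert all(state[sp] == 0 for sp in cmodel.free)


# ---------------------------------------------------------------------------
# Single-step semantics
# ---------------------------------------------------------------------------

def test_update_moves_one_level_toward_target(model, rng):
    # Tr1 sits at 0 with target 2 under dual costimulation: after one step it
    # is at most 1, regardless of whether it fired.
    cmodel = apply_condition(model, Condition.from_treatment("dual"))
    for _ in range(50):
        new = step(cmodel, initial_state(cmodel), p=1.0, rng=rng)
        assert new["Tr1"] == 1
        assert new["Tr5"] == 1


def test_update_fires_with_probability_p(model):
    # Isolate PKB by clamping every other downstream species; from the worked
    # situation (PKB high, Tr2 low, Ox medium) a firing update drops PKB to
    # medium, a non-firing one leaves it high.
    perts = tuple(
        Perturbation(sp, 0)
        for sp in ("Tr1", "Tr2", "Tr5", "Nk", "ERK", "JNK", "Bim", "S", "C")
    )
    cmodel = apply_condition(model, Condition(2, 0, perts))
    assert cmodel.free == ("PKB",)
    state = initial_state(cmodel)
    state.update(PKB=2, Ox=1)  # engine honors the supplied state
    rng = np.random.default_rng(5)
    n, fired = 3000, 0
    for _ in range(n):
        new = step(cmodel, state, p=0.5, rng=rng)
        assert new["PKB"] in (1, 2)
        fired += new["PKB"] == 1
    assert fired / n == pytest.approx(0.5, abs=0.03)


def test_step_rejects_invalid_probability(dual, rng):
    with pytest.raises(ValueError):
        step(dual, initial_state(dual), p=0.0, rng=rng)


def test_fixed_point_is_inert_under_any_update(dual, rng):
    state = analytic_fixed_point(dual)
    for scheme in ("sweep", "single"):
        for _ in range(20):
            assert step(dual, state, p=1.0, rng=rng, scheme=scheme) == state


def test_single_species_scheme_changes_at_most_one_species(dual, rng):
    state = initial_state(dual)
    for _ in range(50):
        new = step(dual, state, p=1.0, rng=rng, scheme="single")
        changed = [sp for sp in state if new[sp] != state[sp]]
        assert len(changed) <= 1


# ---------------------------------------------------------------------------
# Fixed-point predicate and oracles
# ---------------------------------------------------------------------------

def test_resting_state_is_the_none_fixed_point(model):
    cmodel = apply_condition(model, Condition.from_treatment("none"))
    assert is_fixed_point(cmodel, EXPECTED_FIXED_POINTS["none"])
    assert not is_fixed_point(cmodel, initial_state(cmodel))  # JNK target is 1


def test_all_zero_is_not_fixed_under_dual(dual):
    assert not is_fixed_point(dual, initial_state(dual))


@pytest.mark.parametrize("treatment", sorted(EXPECTED_FIXED_POINTS))
def test_each_condition_has_one_fixed_point_matching_hand_derivation(
    model, treatment
):
    cmodel = apply_condition(model, Condition.from_treatment(treatment))
    report = enumerate_fixed_points(cmodel)
    assert report.method == "exhaustive"
    assert len(report.fixed_points) == 1
    assert report.fixed_points[0] == EXPECTED_FIXED_POINTS[treatment]


@pytest.mark.parametrize("treatment", sorted(EXPECTED_FIXED_POINTS))
@pytest.mark.parametrize("perts", SCREEN_PERTURBATIONS, ids=lambda ps: (
    "+".join(p.label for p in ps) or "WT"))
def test_analytic_oracle_equals_exhaustive_enumeration(model, treatment, perts):
    cmodel = apply_condition(model, Condition.from_treatment(treatment, perts))
    report = enumerate_fixed_points(cmodel)
    assert len(report.fixed_points) == 1
    assert analytic_fixed_point(cmodel) == report.fixed_points[0]


def test_identity_rules_make_every_state_fixed():
    m = toy_model({
        "X": (("X",), lambda x: x),
        "Y": (("Y",), lambda y: y),
    })
    cmodel = apply_condition(m, Condition(0, 0))
    report = enumerate_fixed_points(cmodel)
    assert len(report.fixed_points) == 9  # 3^2 free states


def test_analytic_oracle_rejects_cyclic_models():
    m = toy_model({
        "X": (("Y",), lambda y: 2 - y),
        "Y": (("X",), lambda x: 2 - x),
    })
    cmodel = apply_condition(m, Condition(0, 0))
    with pytest.raises(ValueError, match="cyclic"):
        analytic_fixed_point(cmodel)
    # the enumeration oracle still works on the cycle
    points = enumerate_fixed_points(cmodel).fixed_points
    assert {(s["X"], s["Y"]) for s in points} == {(0, 2), (1, 1), (2, 0)}


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@given(
    treatment=st.sampled_from(sorted(EXPECTED_FIXED_POINTS)),
    pert=st.sampled_from(SCREEN_PERTURBATIONS),
    seed=st.integers(0, 10_000),
    p=st.sampled_from([0.2, 0.5, 1.0]),
)
def test_trajectories_are_continuous_and_respect_clamps(
    model, treatment, pert, seed, p
):
    """|Δlevel| <= 1 per step per species; clamped species never move."""
    cmodel = apply_condition(model, Condition.from_treatment(treatment, pert))
    settings = SimulationSettings(p=p, max_steps=80, horizon=20, n_runs=1, seed=seed)
    traj = simulate(cmodel, settings)
    clamped = set(cmodel.clamps)
    for before, after in zip(traj.states, traj.states[1:]):
        for sp in cmodel.model.species:
            assert abs(after[sp] - before[sp]) <= 1
            if sp in clamped:
                assert after[sp] == cmodel.clamps[sp]


def test_simulation_is_absorbed_at_the_fixed_point(dual):
    settings = SimulationSettings(seed=3)
    traj = simulate(dual, settings)
    assert traj.converged_at is not None
    fixed = traj.states[traj.converged_at]
    assert is_fixed_point(dual, fixed)
    assert all(s == fixed for s in traj.states[traj.converged_at:])
    assert len(traj.states) >= settings.horizon + 1


def test_simulation_starting_at_fixed_point_converges_immediately(dual):
    fixed = analytic_fixed_point(dual)
    traj = simulate(dual, SimulationSettings(p=1.0, seed=0), initial=fixed)
    assert traj.converged_at == 0


@pytest.mark.parametrize("treatment", sorted(EXPECTED_FIXED_POINTS))
def test_every_seed_reaches_the_unique_fixed_point(model, treatment):
    cmodel = apply_condition(model, Condition.from_treatment(treatment))
    expected = EXPECTED_FIXED_POINTS[treatment]
    for seed in range(40):
        traj = simulate(cmodel, SimulationSettings(seed=seed))
        assert traj.converged_at is not None
        assert traj.final_state == expected


def test_steady_state_independent_of_initial_conditions(model, rng):
    """Random starting levels do not change where the system settles."""
    for treatment, expected in EXPECTED_FIXED_POINTS.items():
        cmodel = apply_condition(model, Condition.from_treatment(treatment))
        for _ in range(25):
            init = random_initial_state(cmodel, rng)
            traj = simulate(
                cmodel,
                SimulationSettings(seed=int(rng.integers(2**31))),
                initial=init,
            )
            assert traj.final_state == expected, treatment


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------

def test_ensemble_is_seed_deterministic(dual, quick_settings):
    a = run_ensemble(dual, quick_settings)
    b = run_ensemble(dual, quick_settings)
    assert np.array_equal(a.mean, b.mean)
    assert np.array_equal(a.sd, b.sd)
    assert a.converged_at == b.converged_at
    c = run_ensemble(
        dual, SimulationSettings(n_runs=quick_settings.n_runs, seed=99)
    )
    assert not np.array_equal(a.mean, c.mean)


def test_ensemble_step_zero_has_no_spread(dual, quick_settings):
    summary = run_ensemble(dual, quick_settings)
    assert np.all(summary.sd[0] == 0.0)
    init = initial_state(dual)
    assert list(summary.mean[0]) == [init[sp] for sp in summary.species]


def test_dual_ensemble_settles_at_maximal_survival(dual, quick_settings):
    summary = run_ensemble(dual, quick_settings)
    j = summary.species.index("S")
    assert summary.mean[-1, j] == 2.0
    assert summary.sd[-1, j] == 0.0
    assert summary.steady_levels() == EXPECTED_FIXED_POINTS["dual"]


def test_single_run_ensemble_has_zero_sd(dual):
    summary = run_ensemble(dual, SimulationSettings(n_runs=1, seed=4))
    assert np.all(summary.sd == 0.0)


def test_ensemble_to_frame_is_tidy(dual, quick_settings):
    frame = run_ensemble(dual, quick_settings).to_frame()
    assert list(frame.columns) == ["step", "species", "mean", "sd"]
    assert len(frame) == (quick_settings.horizon + 1) * 12


def test_convergence_fraction_is_cumulative(model):
    cmodel = apply_condition(model, Condition.from_treatment("monoI"))
    trajs = [
        simulate(cmodel, SimulationSettings(seed=s)) for s in range(30)
    ]
    fractions = [convergence_fraction(trajs, t) for t in range(0, 60, 5)]
    assert fractions[0] == 0.0  # initial state is not fixed
    assert fractions[-1] == 1.0
    assert all(b >= a for a, b in zip(fractions, fractions[1:]))
    with pytest.raises(ValueError):
        convergence_fraction([], 10)
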