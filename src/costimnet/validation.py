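"""Qualitative steady-state constraints and the model validation suite.

Each constraint encodes one reported or predicted outcome of the
costimulation system — baseline behavior of the four treatments, the
dual-costimulation knockout result (only NF-kB loss lowers survival), and
the knock-out/overexpression response predictions — as a decidable
predicate over the analytic steady-state table. Predicates depend only on
fixed-point levels, never on trajectories, so the suite is seed-free.

"Response to treatment X is abrogated" is formalized as: the readout
under treatment X with the perturbation equals the readout under no
costimulation with the same perturbation.

Constraints the bundled reconstruction is known not to satisfy are
first-class ``known-gap`` entries rather than silently dropped: the suite
stays green when they fail, but a model that does satisfy them (e.g. an
alternative transcription loaded from a model file) gets full credit.
The bundled model's gaps, and why they are structural, are discussed in
the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import pandas as pd

from .model import ModelDefinition, SystemState, default_model, validate_model
from .scenarios import CONDITION_ORDER, steady_state_table

SteadyTable = dict[tuple[str, str], SystemState]
CheckResult = tuple[bool, str]


@dataclass(frozen=True)
class QualitativeConstraint:
    """One assertable steady-state outcome."""

    id: str
    description: str
    expected_for_default: str  # "pass" or "known-gap"
    check: Callable[[SteadyTable], CheckResult]


@dataclass(frozen=True)
class ConstraintResult:
    id: str
    description: str
    expected_for_default: str
    passed: bool
    observed: str


@dataclass(frozen=True)
class ConstraintReport:
    """Outcome of the full suite against one model."""

    results: tuple[ConstraintResult, ...]

    @property
    def green(self) -> bool:
        """True iff every constraint passes or is a declared known-gap."""
        return all(
            r.passed or r.expected_for_default == "known-gap" for r in self.results
        )

    @property
    def failures(self) -> tuple[ConstraintResult, ...]:
        return tuple(r for r in self.results if not r.passed)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": r.id,
                    "description": r.description,
                    "expected_for_default": r.expected_for_default,
                    "status": "pass" if r.passed else "fail",
                    "observed": r.observed,
                }
                for r in self.results
            ]
        )


def _lvl(table: SteadyTable, row: str, treatment: str, species: str) -> int:
    return table[(row, treatment)][species]


def _abrogated(table: SteadyTable, row: str, treatment: str, species: str) -> bool:
    """Readout under treatment equals readout under no costimulation."""
    return _lvl(table, row, treatment, species) == _lvl(table, row, "none", species)


def _obs(table: SteadyTable, row: str, species: str) -> str:
    levels = [
        f"{t}={_lvl(table, row, t, species)}" for t in CONDITION_ORDER
    ]
    return f"{species}[{row}]: " + " ".join(levels)


def builtin_constraints() -> list[QualitativeConstraint]:
    """The built-in suite of qualitative steady-state constraints."""

    def c(id: str, description: str, expected: str, check) -> QualitativeConstraint:
        return QualitativeConstraint(id, description, expected, check)

    def baseline(treatment: str, expectations: dict[str, int]):
        def check(table: SteadyTable) -> CheckResult:
            observed = {
                sp: _lvl(table, "WT", treatment, sp) for sp in expectations
            }
            return observed == expectations, f"{treatment}: {observed}"
        return check

    def monoOx_bim(table: SteadyTable) -> CheckResult:
        bim = _lvl(table, "WT", "monoOx", "Bim")
        return bim in (0, 1), f"monoOx Bim={bim} (moderate decrease expected)"

    def only_nk_ko_lowers_dual_s(table: SteadyTable) -> CheckResult:
        wt = _lvl(table, "WT", "dual", "S")
        lowered = {
            sp: _lvl(table, f"{sp}-KO", "dual", "S") < wt
            for sp in ("ERK", "PKB", "JNK", "Nk")
        }
        ok = lowered == {"ERK": False, "PKB": False, "JNK": False, "Nk": True}
        return ok, f"dual S lowered by KO: {lowered} (WT S={wt})"

    def nk_ko_dual_jnk_bim_rise(table: SteadyTable) -> CheckResult:
        pairs = {
            sp: (_lvl(table, "Nk-KO", "dual", sp), _lvl(table, "WT", "dual", sp))
            for sp in ("JNK", "Bim")
        }
        ok = all(ko > wt for ko, wt in pairs.values())
        return ok, f"dual (Nk-KO, WT) levels: {pairs}"

    def pkb_oe_survival(table: SteadyTable) -> CheckResult:
        s_all_high = all(
            _lvl(table, "PKB-OE", t, "S") == 2 for t in CONDITION_ORDER
        )
        c_levels = {_lvl(table, "PKB-OE", t, "C") for t in CONDITION_ORDER}
        ok = s_all_high and len(c_levels) > 1
        return ok, _obs(table, "PKB-OE", "S") + "; " + _obs(table, "PKB-OE", "C")

    def nk_oe_maximal(table: SteadyTable) -> CheckResult:
        ok = all(
            _lvl(table, "Nk-OE", t, sp) == 2
            for t in CONDITION_ORDER
            for sp in ("S", "C")
        )
        return ok, _obs(table, "Nk-OE", "S") + "; " + _obs(table, "Nk-OE", "C")

    def pkb_ko_abrogates_monoOx_s(table: SteadyTable) -> CheckResult:
        ok = _abrogated(table, "PKB-KO", "monoOx", "S")
        return ok, _obs(table, "PKB-KO", "S")

    def nk_ko_abrogations(table: SteadyTable) -> CheckResult:
        ok = _abrogated(table, "Nk-KO", "monoI", "S") and _abrogated(
            table, "Nk-KO", "monoOx", "C"
        )
        return ok, _obs(table, "Nk-KO", "S") + "; " + _obs(table, "Nk-KO", "C")

    def erk_ko_abrogates_monoI_s(table: SteadyTable) -> CheckResult:
        return _abrogated(table, "ERK-KO", "monoI", "S"), _obs(table, "ERK-KO", "S")

    def erk_ko_abrogates_monoOx_s(table: SteadyTable) -> CheckResult:
        return _abrogated(table, "ERK-KO", "monoOx", "S"), _obs(table, "ERK-KO", "S")

    def jnk_oe_abrogates_mono_s(table: SteadyTable) -> CheckResult:
        ok = _abrogated(table, "JNK-OE", "monoI", "S") and _abrogated(
            table, "JNK-OE", "monoOx", "S"
        )
        return ok, _obs(table, "JNK-OE", "S")

    def jnk_oe_raises_cytokine(table: SteadyTable) -> CheckResult:
        raised = {
            t: (
                _lvl(table, "JNK-OE", t, "C"),
                _lvl(table, "WT", t, "C"),
            )
            for t in ("monoI", "monoOx", "dual")
        }
        ok = all(oe > wt for oe, wt in raised.values())
        return ok, f"C (JNK-OE, WT) by treatment: {raised}"

    return [
        c(
            "baseline-none-survival-minimal",
            "No costimulation: survival and cytokine release at their lowest level",
            "pass",
            baseline("none", {"S": 0, "C": 0}),
        ),
        c(
            "baseline-none-jnk-intermediate",
            "No costimulation: JNK neither TRAF2-activated nor NF-kB-inhibited, "
            "so it holds an intermediate level",
            "pass",
            baseline("none", {"JNK": 1}),
        ),
        c(
            "baseline-none-nfkb-low-bim-high",
            "No costimulation: NF-kB at its lowest level and Bim at its highest",
            "pass",
            baseline("none", {"Nk": 0, "Bim": 2}),
        ),
        c(
            "baseline-monoI-moderate-response",
            "4-1BB mono-costimulation: moderate survival and cytokine increase "
            "via moderate NF-kB",
            "pass",
            baseline("monoI", {"S": 1, "C": 1, "Nk": 1}),
        ),
        c(
            "baseline-monoOx-moderate-response",
            "OX40 mono-costimulation: moderate survival and cytokine increase, "
            "PKB elevated, Bim moderately decreased",
            "pass",
            baseline("monoOx", {"S": 1, "C": 1, "PKB": 1}),
        ),
        c(
            "baseline-monoOx-bim-decrease",
            "OX40 mono-costimulation: Bim decreased from its resting high level",
            "pass",
            monoOx_bim,
        ),
        c(
            "baseline-dual-maximal-response",
            "Dual costimulation: highest survival and cytokine levels via high "
            "NF-kB and PKB with low Bim",
            "pass",
            baseline("dual", {"S": 2, "C": 2, "Nk": 2, "Bim": 0}),
        ),
        c(
            "dual-ko-only-nfkb-lowers-survival",
            "Of ERK/PKB/JNK/NF-kB knockouts under dual costimulation, only the "
            "NF-kB knockout lowers steady-state survival",
            "pass",
            only_nk_ko_lowers_dual_s,
        ),
        c(
            "nfkb-ko-dual-jnk-bim-rise",
            "NF-kB knockout under dual costimulation releases JNK and Bim above "
            "their dual wild-type levels",
            "pass",
            nk_ko_dual_jnk_bim_rise,
        ),
        c(
            "pkb-oe-survival-treatment-independent",
            "PKB overexpression: maximal survival in every treatment while the "
            "cytokine response still depends on treatment",
            "pass",
            pkb_oe_survival,
        ),
        c(
            "nfkb-oe-maximal-everywhere",
            "NF-kB overexpression: maximal survival and cytokine release in "
            "every treatment",
            "pass",
            nk_oe_maximal,
        ),
        c(
            "pkb-ko-abrogates-monoOx-survival",
            "PKB knockout abrogates the survival response to OX40 "
            "mono-costimulation",
            "pass",
            pkb_ko_abrogates_monoOx_s,
        ),
        c(
            "nfkb-ko-abrogates-monoI-survival-monoOx-cytokine",
            "NF-kB knockout abrogates the survival response to 4-1BB and the "
            "cytokine response to OX40",
            "pass",
            nk_ko_abrogations,
        ),
        c(
            "erk-ko-abrogates-monoI-survival",
            "ERK knockout abrogates the survival response to 4-1BB "
            "mono-costimulation",
            "pass",
            erk_ko_abrogates_monoI_s,
        ),
        c(
            "erk-ko-abrogates-monoOx-survival",
            "ERK knockout abrogates the survival response to OX40 "
            "mono-costimulation (unreachable while ERK is driven solely by "
            "TRAF1, which OX40 does not engage)",
            "known-gap",
            erk_ko_abrogates_monoOx_s,
        ),
        c(
            "jnk-oe-abrogates-mono-survival",
            "JNK overexpression abrogates both mono-costimulation survival "
            "responses",
            "known-gap",
            jnk_oe_abrogates_mono_s,
        ),
        c(
            "jnk-oe-raises-cytokine-in-stimulated",
            "JNK overexpression raises cytokine release above wild type in "
            "stimulated treatments",
            "known-gap",
            jnk_oe_raises_cytokine,
        ),
    ]


def evaluate_constraints(
    model: ModelDefinition | None = None,
) -> ConstraintReport:
    """Score every built-in constraint against a model's steady states.

    The model must validate cleanly (total, in-range tables); steady
    states are taken from the analytic fixed-point oracle, so the report
    is deterministic and seed-independent.
    """
    model = model or default_model()
    validation = validate_model(model)
    if not validation.ok:
        raise ValueError(
            "model fails validation: " + "; ".join(validation.issues[:5])
        )
    table = steady_state_table(model)
    results = []
    for constraint in builtin_constraints():
        passed, observed = constraint.check(table)
        results.append(
            ConstraintResult(
                id=constraint.id,
                description=constraint.description,
                expected_for_default=constraint.expected_for_default,
                passed=bool(passed),
                observed=observed,
            )
        )
    return ConstraintReport(results=tuple(results))
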