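"""Pre-packaged experiment grids: baseline panel, knockout panel, screen.

The screen sweeps knock-out and overexpression of the four druggable
downstream nodes (ERK, PKB, JNK, NF-kB) against the four costimulation
treatments and tabulates the steady-state survival and cytokine levels.
Steady states come from the analytic fixed-point oracle (unique for the
bundled acyclic model); each entry can additionally be confirmed by the
modal final state of a stochastic ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .engine import (
    EnsembleSummary,
    SimulationSettings,
    analytic_fixed_point,
    run_ensemble,
)
from .model import (
    Condition,
    ModelDefinition,
    Perturbation,
    SystemState,
    apply_condition,
    default_model,
)

#: Screen rows: wild type plus KO/OE of each druggable node.
ROW_ORDER: tuple[str, ...] = (
    "WT",
    "ERK-KO", "PKB-KO", "JNK-KO", "Nk-KO",
    "ERK-OE", "PKB-OE", "JNK-OE", "Nk-OE",
)

#: Screen columns: the four costimulation treatments.
CONDITION_ORDER: tuple[str, ...] = ("none", "monoI", "monoOx", "dual")

#: The four druggable downstream nodes targeted by the screen.
SCREEN_TARGETS: tuple[str, ...] = ("ERK", "PKB", "JNK", "Nk")


def row_perturbations(row: str) -> tuple[Perturbation, ...]:
    """Perturbation clamps for one screen row label ('WT', 'Nk-KO', ...)."""
    if row == "WT":
        return ()
    species, kind = row.rsplit("-", 1)
    level = {"KO": 0, "OE": 2}[kind]
    return (Perturbation(species, level),)


def baseline_panel(
    settings: SimulationSettings, model: ModelDefinition | None = None
) -> dict[str, EnsembleSummary]:
    """Unperturbed ensembles for each of the four costimulation treatments."""
    model = model or default_model()
    return {
        treatment: run_ensemble(
            apply_condition(model, Condition.from_treatment(treatment)), settings
        )
        for treatment in CONDITION_ORDER
    }


def dual_knockout_panel(
    settings: SimulationSettings, model: ModelDefinition | None = None
) -> dict[str, EnsembleSummary]:
    """Dual-costimulation ensembles with single knockouts of the screen targets."""
    model = model or default_model()
    return {
        sp: run_ensemble(
            apply_condition(
                model,
                Condition.from_treatment("dual", (Perturbation(sp, 0),)),
            ),
            settings,
        )
        for sp in SCREEN_TARGETS
    }


def steady_state_table(
    model: ModelDefinition | None = None,
) -> dict[tuple[str, str], SystemState]:
    """Analytic fixed point for every (screen row, treatment) pair."""
    model = model or default_model()
    table: dict[tuple[str, str], SystemState] = {}
    for row in ROW_ORDER:
        perts = row_perturbations(row)
        for treatment in CONDITION_ORDER:
            cmodel = apply_condition(
                model, Condition.from_treatment(treatment, perts)
            )
            table[(row, treatment)] = analytic_fixed_point(cmodel)
    return table


@dataclass(frozen=True)
class PerturbationScreen:
    """Steady-state survival and cytokine matrices over the screen grid."""

    survival: pd.DataFrame  # rows = perturbations, columns = treatments
    cytokine: pd.DataFrame
    steady_states: dict[tuple[str, str], SystemState]


def perturbation_screen(
    settings: SimulationSettings,
    model: ModelDefinition | None = None,
    confirm: bool = True,
) -> PerturbationScreen:
    """Compute the 9 x 4 survival and cytokine response matrices.

    Entries are the steady-state levels from the analytic oracle. With
    ``confirm=True`` each entry is re-derived as the modal final level of
    a stochastic ensemble under ``settings``; a mismatch raises
    ``RuntimeError`` (it would mean the simulation does not settle into
    the oracle's fixed point).
    """
    model = model or default_model()
    table = steady_state_table(model)

    def matrix(readout: str) -> pd.DataFrame:
        data = {
            treatment: [table[(row, treatment)][readout] for row in ROW_ORDER]
            for treatment in CONDITION_ORDER
        }
        return pd.DataFrame(data, index=list(ROW_ORDER), dtype=int)

    if confirm:
        for row in ROW_ORDER:
            perts = row_perturbations(row)
            for treatment in CONDITION_ORDER:
                cmodel = apply_condition(
                    model, Condition.from_treatment(treatment, perts)
                )
                modal = run_ensemble(cmodel, settings).steady_levels()
                for readout in ("S", "C"):
                    if modal[readout] != table[(row, treatment)][readout]:
                        raise RuntimeError(
                            f"ensemble mode disagrees with fixed point for "
                            f"{readout} at ({row}, {treatment}): "
                            f"{modal[readout]} != {table[(row, treatment)][readout]}"
                        )
    return PerturbationScreen(
        survival=matrix("S"), cytokine=matrix("C"), steady_states=table
    )
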