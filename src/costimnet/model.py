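"""Multistate logic model of CD8 T cell costimulatory signaling.

The network couples the two TNFR-family costimulatory inputs, 4-1BB/CD137
(``I``) and OX40/CD134 (``Ox``), to the TRAF adaptor proteins (``Tr1``,
``Tr2``, ``Tr5``), the transcription factor NF-kB (``Nk``), the kinases
``PKB`` (AKT), ``ERK`` and ``JNK``, the pro-apoptotic protein ``Bim``, and
two phenotypic readouts: cell survival (``S``) and cytokine release
(``C``). TCR triggering is assumed optimal and is therefore implicit.

Every species carries an ordinal activity level, 0 (low), 1 (medium) or 2
(high). Each non-input species owns a *total* transition table mapping its
parents' current levels to a target level; the tables are the model, and
the closed-form expressions in :func:`default_model` exist only to
generate them. Knock-out and overexpression are expressed as clamps that
hold a species at level 0 or 2 for an entire simulation, which is also how
the four costimulation conditions (none / mono-I / mono-Ox / dual) fix the
two inputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import cached_property
from typing import Callable, Mapping

import networkx as nx
import numpy as np

#: The three ordinal activity levels: low, medium, high.
LEVELS: tuple[int, int, int] = (0, 1, 2)

#: Canonical species order of the bundled model.
SPECIES: tuple[str, ...] = (
    "I", "Ox", "Tr1", "Tr2", "Tr5", "Nk", "PKB", "ERK", "JNK", "Bim", "S", "C",
)

#: The two receptor inputs; they have no update rules and are always clamped.
INPUTS: tuple[str, str] = ("I", "Ox")

#: A system state: one activity level per species.
SystemState = dict[str, int]

#: The four canonical costimulation treatments as (I, Ox) clamp levels.
TREATMENTS: dict[str, tuple[int, int]] = {
    "none": (0, 0),
    "monoI": (2, 0),
    "monoOx": (0, 2),
    "dual": (2, 2),
}


def clamp_level(x: int) -> int:
    """Clip an integer onto the 0..2 activity scale."""
    return 0 if x < 0 else 2 if x > 2 else int(x)


def _check_level(value: int, what: str = "level") -> int:
    if value not in LEVELS:
        raise ValueError(f"{what} must be one of {LEVELS}, got {value!r}")
    return int(value)


@dataclass(frozen=True)
class UpdateRule:
    """A total transition table for one species.

    Parameters
    ----------
    target
        The species this rule updates.
    parents
        Ordered parent species; the table is keyed by their level tuples.
    table
        Mapping from every element of ``{0,1,2}^len(parents)`` to a target
        activity level.
    """

    target: str
    parents: tuple[str, ...]
    table: Mapping[tuple[int, ...], int]

    @classmethod
    def from_function(
        cls, target: str, parents: tuple[str, ...], fn: Callable[..., int]
    ) -> "UpdateRule":
        """Enumerate ``fn`` over all parent-level tuples into an explicit table."""
        table = {
            combo: _check_level(fn(*combo), f"{target} table output")
            for combo in itertools.product(LEVELS, repeat=len(parents))
        }
        return cls(target=target, parents=tuple(parents), table=table)

    def evaluate(self, state: Mapping[str, int]) -> int:
        """Look up the target level at the parents' current levels."""
        key = tuple(int(state[p]) for p in self.parents)
        try:
            return self.table[key]
        except KeyError:
            raise KeyError(
                f"rule for {self.target!r} has no entry for "
                f"{self.parents} = {key}"
            ) from None

    def as_array(self) -> np.ndarray:
        """The table as an int8 array of shape ``(3,) * len(parents)``.

        Missing entries (only possible for hand-built, defective tables)
        are filled with -1.
        """
        arr = np.full((3,) * len(self.parents), -1, dtype=np.int8)
        for combo, out in self.table.items():
            if all(level in LEVELS for level in combo):
                arr[combo] = out
        return arr


@dataclass(frozen=True)
class ModelDefinition:
    """A complete model: species list, designated inputs, one rule per species."""

    species: tuple[str, ...]
    inputs: tuple[str, ...]
    rules: Mapping[str, UpdateRule]

    @property
    def updatable(self) -> tuple[str, ...]:
        """Species that carry an update rule (everything except the inputs)."""
        return tuple(s for s in self.species if s not in self.inputs)

    def dependency_graph(self) -> nx.DiGraph:
        """Directed graph with an edge parent -> target for every rule input."""
        g = nx.DiGraph()
        g.add_nodes_from(self.species)
        for rule in self.rules.values():
            for parent in rule.parents:
                g.add_edge(parent, rule.target)
        return g

    @property
    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.dependency_graph())


@dataclass(frozen=True)
class Perturbation:
    """A knock-out (level 0) or overexpression (level 2) clamp on one species."""

    species: str
    level: int

    def __post_init__(self) -> None:
        if self.level not in (0, 2):
            raise ValueError(
                "perturbation clamps are knock-out (0) or overexpression (2); "
                f"got level {self.level!r} for {self.species!r}"
            )

    @property
    def label(self) -> str:
        return f"{self.species}-{'KO' if self.level == 0 else 'OE'}"


@dataclass(frozen=True)
class Condition:
    """Input clamp levels plus an optional list of perturbation clamps."""

    i_level: int
    ox_level: int
    perturbations: tuple[Perturbation, ...] = ()

    def __post_init__(self) -> None:
        for name, lvl in (("I", self.i_level), ("Ox", self.ox_level)):
            if lvl not in (0, 2):
                raise ValueError(
                    f"input {name} must be clamped low (0) or high (2), got {lvl!r}"
                )
        object.__setattr__(self, "perturbations", tuple(self.perturbations))
        seen: set[str] = set()
        for pert in self.perturbations:
            if pert.species in seen:
                raise ValueError(f"duplicate perturbation for {pert.species!r}")
            seen.add(pert.species)

    @classmethod
    def from_treatment(
        cls, treatment: str, perturbations: tuple[Perturbation, ...] = ()
    ) -> "Condition":
        try:
            i_level, ox_level = TREATMENTS[treatment]
        except KeyError:
            raise ValueError(
                f"unknown treatment {treatment!r}; expected one of {sorted(TREATMENTS)}"
            ) from None
        return cls(i_level, ox_level, tuple(perturbations))

    @property
    def treatment(self) -> str:
        """Canonical treatment label for the (I, Ox) clamp pair."""
        for label, pair in TREATMENTS.items():
            if pair == (self.i_level, self.ox_level):
                return label
        raise AssertionError("unreachable: input levels restricted to {0, 2}")

    @property
    def label(self) -> str:
        parts = [self.treatment] + [p.label for p in self.perturbations]
        return "+".join(parts)


@dataclass(frozen=True)
class ConstrainedModel:
    """A model viewed under a condition: inputs and perturbed species clamped.

    A clamped species' target always equals its clamp level, so it never
    moves; all other rules are untouched.
    """

    model: ModelDefinition
    condition: Condition

    @cached_property
    def clamps(self) -> dict[str, int]:
        clamps = {"I": self.condition.i_level, "Ox": self.condition.ox_level}
        for pert in self.condition.perturbations:
            clamps[pert.species] = pert.level
        return clamps

    @cached_property
    def free(self) -> tuple[str, ...]:
        """Updatable species not held by a clamp, in model species order."""
        return tuple(
            s for s in self.model.species
            if s not in self.clamps and s not in self.model.inputs
        )

    def target_level(self, state: Mapping[str, int], species: str) -> int:
        """The level ``species`` is driven toward from ``state``.

        Clamped species (inputs included) report their clamp; free species
        report their rule-table lookup.
        """
        if species not in self.model.species:
            raise KeyError(f"unknown species {species!r}")
        if species in self.clamps:
            return self.clamps[species]
        if species in self.model.inputs:
            raise ValueError(f"input {species!r} has no update rule")
        return self.model.rules[species].evaluate(state)


def target_level(
    model: ModelDefinition | ConstrainedModel, state: Mapping[str, int], species: str
) -> int:
    """Rule-table lookup for ``species`` at the parents' current levels."""
    if isinstance(model, ConstrainedModel):
        return model.target_level(state, species)
    if species not in model.species:
        raise KeyError(f"unknown species {species!r}")
    if species in model.inputs:
        raise ValueError(f"input {species!r} has no update rule; clamp it instead")
    return model.rules[species].evaluate(state)


# ---------------------------------------------------------------------------
# The bundled default model
# ---------------------------------------------------------------------------

def _tr1(i: int) -> int:
    # TRAF1 is recruited by 4-1BB; activity proportional to I.
    return i


def _tr5(ox: int) -> int:
    # TRAF5 is recruited by OX40; activity proportional to Ox.
    return ox


def _stim_t(i: int, ox: int) -> int:
    # Receptor drive onto TRAF2. 4-1BB dominates: OX40 alone saturates at 1,
    # standing in for TRAF3 competing with TRAF2 for OX40 binding.
    return min(2, i + ox // 2)


def _tr2(i: int, ox: int, tr1: int) -> int:
    # TRAF1 boosts the receptor drive by one level (or mitigates it when absent).
    return clamp_level(_stim_t(i, ox) + (tr1 - 1))


def _nk(tr2: int, tr5: int) -> int:
    # Canonical NF-kB activation, TRAF2 weighted twice as strongly as TRAF5.
    return (2 * tr2 + tr5 + 1) // 3


def _pkb(tr2: int, ox: int) -> int:
    # PI3K/PKB axis engaged by OX40 and by TRAF2.
    return (tr2 + ox) // 2


def _erk(tr1: int) -> int:
    # ERK carries the TRAF1-dependent arm of Bim suppression.
    return tr1


def _jnk(tr2: int, nk: int) -> int:
    # Balance between the TRAF2-driven MAPK cascade and transcriptional
    # inhibition by NF-kB.
    return clamp_level(1 + tr2 - nk)


def _inh_b(erk: int, pkb: int) -> int:
    # Combined Bim-inhibitory drive: ERK-dependent and PKB/FoxO arms.
    return max(erk, pkb)


def _bim(jnk: int, erk: int, pkb: int) -> int:
    # Bim: activated by JNK, opposed by the stronger of its two inhibitors.
    return clamp_level(1 + jnk - _inh_b(erk, pkb))


def _survival(nk: int, pkb: int, bim: int, jnk: int) -> int:
    # Survival as a balance of pro-survival (NF-kB, PKB) and pro-apoptotic
    # (Bim, JNK) drives. Full survival needs one activator saturated and the
    # activators at least matching the inhibitors; survival collapses when
    # activation is weak or inhibitors dominate by two levels or more.
    act, inh = nk + pkb, bim + jnk
    if max(nk, pkb) == 2 and act - inh >= 0:
        return 2
    if act < 2 or act - inh <= -2:
        return 0
    return 1


def _cytokine(nk: int, jnk: int) -> int:
    # NF-kB is the dominant driver of cytokine genes; JNK contributes, but a
    # moderate JNK level with low NF-kB is not sufficient for moderate output.
    if nk == 0:
        return 1 if jnk == 2 else 0
    return 2 if nk == 2 else 1


def default_model() -> ModelDefinition:
    """The bundled 12-species costimulation model.

    Rules are stored as explicit, fully enumerated transition tables; the
    closed forms in this module are used only to generate them. The helper
    quantities ``stim_T`` (receptor drive onto TRAF2, inside the Tr2 rule)
    and ``inh_B`` (combined Bim-inhibitor level, inside the Bim rule) are
    rule-construction devices, not state variables.
    """
    rules = {
        "Tr1": UpdateRule.from_function("Tr1", ("I",), _tr1),
        "Tr5": UpdateRule.from_function("Tr5", ("Ox",), _tr5),
        "Tr2": UpdateRule.from_function("Tr2", ("I", "Ox", "Tr1"), _tr2),
        "Nk": UpdateRule.from_function("Nk", ("Tr2", "Tr5"), _nk),
        "PKB": UpdateRule.from_function("PKB", ("Tr2", "Ox"), _pkb),
        "ERK": UpdateRule.from_function("ERK", ("Tr1",), _erk),
        "JNK": UpdateRule.from_function("JNK", ("Tr2", "Nk"), _jnk),
        "Bim": UpdateRule.from_function("Bim", ("JNK", "ERK", "PKB"), _bim),
        "S": UpdateRule.from_function("S", ("Nk", "PKB", "Bim", "JNK"), _survival),
        "C": UpdateRule.from_function("C", ("Nk", "JNK"), _cytokine),
    }
    return ModelDefinition(species=SPECIES, inputs=INPUTS, rules=rules)


# ---------------------------------------------------------------------------
# Validation and condition application
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelValidation:
    """Outcome of :func:`validate_model`: issues plus an acyclicity flag."""

    issues: tuple[str, ...]
    acyclic: bool

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_model(model: ModelDefinition) -> ModelValidation:
    """Check rule totality, output range, and rule/species bookkeeping.

    Acyclicity of the dependency graph is reported as information, not as
    an error: cyclic models are legal, they just lose the closed-form
    fixed-point oracle.
    """
    issues: list[str] = []
    updatable = set(model.updatable)
    for sp in model.inputs:
        if sp not in model.species:
            issues.append(f"input {sp!r} is not a declared species")
        if sp in model.rules:
            issues.append(f"input {sp!r} must not have an update rule")
    for sp in sorted(updatable - set(model.rules)):
        issues.append(f"species {sp!r} has no update rule")
    for name, rule in model.rules.items():
        if name != rule.target:
            issues.append(f"rule keyed {name!r} targets {rule.target!r}")
        for parent in rule.parents:
            if parent not in model.species:
                issues.append(f"rule for {name!r}: unknown parent {parent!r}")
        expected = set(itertools.product(LEVELS, repeat=len(rule.parents)))
        keys = set(rule.table)
        for combo in sorted(expected - keys):
            issues.append(f"rule for {name!r}: table not total, missing {combo}")
        for combo in sorted(keys - expected):
            issues.append(f"rule for {name!r}: spurious table key {combo}")
        for combo in sorted(keys & expected):
            if rule.table[combo] not in LEVELS:
                issues.append(
                    f"rule for {name!r}: output out of range at {combo}: "
                    f"{rule.table[combo]!r}"
                )
    return ModelValidation(issues=tuple(issues), acyclic=model.is_acyclic)


def apply_condition(model: ModelDefinition, condition: Condition) -> ConstrainedModel:
    """Fix the inputs at the condition's levels and clamp perturbed species."""
    for pert in condition.perturbations:
        if pert.species not in model.species:
            raise KeyError(f"perturbation targets unknown species {pert.species!r}")
    return ConstrainedModel(model=model, condition=condition)
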