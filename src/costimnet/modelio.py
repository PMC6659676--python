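"""Plain-text model files, run configuration, and tabular output writers.

Model file format — one section per species, full table spelled out::

    # costimnet multistate logic model
    species: I Ox Tr1 Tr2 Tr5 Nk PKB ERK JNK Bim S C
    inputs: I Ox

    [Tr1]
    parents: I
    0 -> 0
    1 -> 1
    2 -> 2

Rows are written in lexicographic parent-tuple order so writing is
deterministic and the read/write round trip is loss-free. The bundled
default model ships both as code (:func:`costimnet.model.default_model`)
and as ``data/default.model`` in this format.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from .engine import SimulationSettings
from .model import (
    INPUTS,
    Condition,
    ModelDefinition,
    Perturbation,
    TREATMENTS,
    UpdateRule,
)

_BUNDLED_MODEL = "default.model"


def write_model_text(model: ModelDefinition) -> str:
    """Serialize a model to the sectioned key-value text format."""
    lines = [
        "# costimnet multistate logic model",
        "species: " + " ".join(model.species),
        "inputs: " + " ".join(model.inputs),
    ]
    for sp in model.species:
        if sp in model.inputs:
            continue
        rule = model.rules[sp]
        lines.append("")
        lines.append(f"[{sp}]")
        lines.append("parents: " + " ".join(rule.parents))
        for combo in sorted(rule.table):
            lines.append(
                " ".join(str(level) for level in combo)
                + " -> "
                + str(rule.table[combo])
            )
    return "\n".join(lines) + "\n"


def write_model_file(model: ModelDefinition, path: str | Path) -> None:
    Path(path).write_text(write_model_text(model))


def read_model_text(text: str) -> ModelDefinition:
    """Parse the sectioned key-value model format."""
    species: tuple[str, ...] | None = None
    inputs: tuple[str, ...] | None = None
    rules: dict[str, UpdateRule] = {}
    current: str | None = None
    parents: tuple[str, ...] | None = None
    table: dict[tuple[int, ...], int] = {}

    def flush() -> None:
        nonlocal current, parents, table
        if current is not None:
            if parents is None:
                raise ValueError(f"section [{current}] has no 'parents:' line")
            rules[current] = UpdateRule(current, parents, dict(table))
        current, parents, table = None, None, {}

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            flush()
            current = line[1:-1].strip()
            continue
        key, sep, rest = line.partition(":")
        if sep and key.strip() in ("species", "inputs") and current is None:
            values = tuple(rest.split())
            if key.strip() == "species":
                species = values
            else:
                inputs = values
            continue
        if sep and key.strip() == "parents" and current is not None:
            parents = tuple(rest.split())
            continue
        if "->" in line and current is not None:
            left, _, right = line.partition("->")
            try:
                combo = tuple(int(tok) for tok in left.split())
                out = int(right.strip())
            except ValueError:
                raise ValueError(f"line {lineno}: cannot parse table row {raw!r}")
            table[combo] = out
            continue
        raise ValueError(f"line {lineno}: cannot parse {raw!r}")
    flush()
    if species is None:
        raise ValueError("model file is missing the 'species:' line")
    if inputs is None:
        inputs = INPUTS
    return ModelDefinition(species=species, inputs=inputs, rules=rules)


def read_model_file(path: str | Path) -> ModelDefinition:
    return read_model_text(Path(path).read_text())


def bundled_default_model() -> ModelDefinition:
    """The shipped default model, parsed from the packaged model file."""
    text = (
        resources.files("costimnet") / "data" / _BUNDLED_MODEL
    ).read_text()
    return read_model_text(text)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run bit-for-bit."""

    model: str = "default"  # "default" or a model file path
    condition: str = "dual"
    ko: tuple[str, ...] = ()
    oe: tuple[str, ...] = ()
    p: float = 0.5
    runs: int = 100
    steps: int = 200
    horizon: int = 30
    seed: int = 0
    scheme: str = "sweep"
    out: str = "results"

    def settings(self) -> SimulationSettings:
        return SimulationSettings(
            p=self.p,
            max_steps=self.steps,
            horizon=self.horizon,
            n_runs=self.runs,
            seed=self.seed,
            scheme=self.scheme,
        )

    def load_model(self) -> ModelDefinition:
        if self.model == "default":
            return bundled_default_model()
        return read_model_file(self.model)

    def build_condition(self) -> Condition:
        perts = tuple(
            [Perturbation(sp, 0) for sp in self.ko]
            + [Perturbation(sp, 2) for sp in self.oe]
        )
        return Condition.from_treatment(self.condition, perts)

    def echo(self) -> dict[str, Any]:
        return asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration, validating values and filling defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping, got {type(raw).__name__}")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("ko", "oe"):
        if key in raw:
            value = raw[key]
            raw[key] = tuple([value] if isinstance(value, str) else value)
    config = RunConfig(**raw)
    if config.condition not in TREATMENTS:
        raise ValueError(
            f"unknown condition {config.condition!r}; "
            f"expected one of {sorted(TREATMENTS)}"
        )
    config.settings()  # bounds-check p, steps, horizon, runs, scheme
    model = config.load_model()
    for sp in (*config.ko, *config.oe):
        if sp not in model.species:
            raise ValueError(f"unknown species in perturbation list: {sp!r}")
    config.build_condition()  # duplicate/level checks
    return config


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------

def write_sidecar(path: str | Path, payload: dict[str, Any]) -> None:
    """JSON sidecar with the config echo, seed and any run statistics."""
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def state_to_row(state: dict[str, int], species: tuple[str, ...]) -> list[int]:
    return [state[sp] for sp in species]
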