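"""Local sensitivity analysis of model outputs to rate constants and
initial conditions.

Sensitivities are computed by central finite differences on a
multiplicative (log-scaled) perturbation of each input: with step factor
``h = 1 + rel_step`` the entry for input ``x`` and output ``f`` is the
log-log sensitivity

    s = (ln f(x*h) - ln f(x/h)) / (2 ln h)      [both outputs positive]

which estimates d ln f / d ln x, i.e. percent change of the output per
percent change of the input.  When a perturbed output is zero or negative
the entry falls back to the semi-relative (input-scaled) sensitivity
``(f(x*h) - f(x/h)) / (h - 1/h)`` = d f / d ln x and the entry is flagged
``semi-relative``.  Inputs whose nominal value is zero have no defined
multiplicative perturbation; they yield a 0 entry flagged ``zero-input``.
A failed simulation at a perturbed point yields NaN flagged ``failed``.

Each input costs two simulations; the scheme and step size are recorded in
the result's metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import math

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SimulationError
from .network import ReactionNetwork
from .simulate import APOPTOSIS, SimulationSettings, simulate, write_csv

RATE_CONSTANTS = "rate_constants"
INITIAL_CONDITIONS = "initial_conditions"


@dataclass(frozen=True)
class SensitivityMatrix:
    """Normalised local sensitivities: one row per input, one column per output.

    ``values`` holds the sensitivities, ``flags`` per-entry annotations
    ("" for a clean log-log entry), ``metadata`` the step scheme and size.
    """

    values: pd.DataFrame
    flags: pd.DataFrame
    metadata: Dict[str, object] = field(default_factory=dict)

    @property
    def inputs(self) -> List[str]:
        return list(self.values.index)

    @property
    def outputs(self) -> List[str]:
        return list(self.values.columns)

    def to_csv(self, path: Union[str, Path]) -> None:
        frame = self.values.reset_index(names="input")
        write_csv(frame, path)

    def ranking_report(self, output: str) -> dict:
        ranking = rank_parameters(self, output)
        return {
            "output": output,
            "metadata": dict(self.metadata),
            "ranking": [
                {"input": name, "abs_sensitivity": s} for name, s in ranking
            ],
        }


def _resolve_inputs(network: ReactionNetwork, inputs) -> List[Tuple[str, str]]:
    """Return [(kind, id)] with kind in {"parameter", "species"}."""
    if inputs == RATE_CONSTANTS:
        return [("parameter", k) for k in sorted(network.parameters.values)]
    if inputs == INITIAL_CONDITIONS:
        # Only species with a nonzero initial value: a multiplicative
        # perturbation of an exact zero is the identity.
        return [
            ("species", s.name) for s in network.species if s.initial_value > 0
        ]
    resolved = []
    for name in inputs:
        if name in network.parameters:
            resolved.append(("parameter", name))
        elif any(s.name == name for s in network.species):
            resolved.append(("species", name))
        else:
            raise ConfigurationError(
                f"unknown sensitivity input {name!r} (neither a rate "
                "constant nor a species)"
            )
    return resolved


def _resolve_outputs(network: ReactionNetwork, outputs) -> List[str]:
    if outputs == "all":
        return [s.name for s in network.dynamic_species]
    if isinstance(outputs, str):
        outputs = [outputs]
    index = network.species_index
    for name in outputs:
        if name not in index:
            raise ConfigurationError(f"unknown output species {name!r}")
    return list(outputs)


def _scaled(network: ReactionNetwork, kind: str, name: str, factor: float):
    if kind == "parameter":
        return network.with_parameters({name: network.parameters[name] * factor})
    sp = network.species_by_name(name)
    return network.with_initial_values({name: sp.initial_value * factor})


def local_sensitivities(
    network: ReactionNetwork,
    inputs=RATE_CONSTANTS,
    outputs=APOPTOSIS,
    settings: Optional[SimulationSettings] = None,
    rel_step: float = 0.01,
) -> SensitivityMatrix:
    """Finite-difference local sensitivities of end-of-horizon outputs.

    ``inputs`` is ``"rate_constants"``, ``"initial_conditions"``, or an
    explicit list of rate-constant ids / species names.  ``outputs`` is a
    species name, a list of names, or ``"all"``.
    """
    if not 0 < rel_step <= 0.3:
        raise ConfigurationError("rel_step must be in (0, 0.3]")
    settings = settings or SimulationSettings()
    in_specs = _resolve_inputs(network, inputs)
    out_names = _resolve_outputs(network, outputs)
    h = 1.0 + rel_step
    t_end = settings.t_end

    values = np.zeros((len(in_specs), len(out_names)))
    flags = np.full(values.shape, "", dtype=object)
    for i, (kind, name) in enumerate(in_specs):
        nominal = (
            network.parameters[name]
            if kind == "parameter"
            else network.species_by_name(name).initial_value
        )
        if nominal == 0:
            flags[i, :] = "zero-input"
            continue
        try:
            up = simulate(_scaled(network, kind, name, h), settings)
            dn = simulate(_scaled(network, kind, name, 1.0 / h), settings)
        except SimulationError as exc:
            values[i, :] = np.nan
            flags[i, :] = f"failed: {exc}"
            continue
        for j, out in enumerate(out_names):
            f_up = up.value(out, t_end)
            f_dn = dn.value(out, t_end)
            if f_up > 0 and f_dn > 0:
                values[i, j] = (math.log(f_up) - math.log(f_dn)) / (2 * math.log(h))
            else:
                values[i, j] = (f_up - f_dn) / (h - 1.0 / h)
                flags[i, j] = "semi-relative"

    index = [name for _, name in in_specs]
    return SensitivityMatrix(
        values=pd.DataFrame(values, index=index, columns=out_names),
        flags=pd.DataFrame(flags, index=index, columns=out_names),
        metadata={
            "scheme": "central multiplicative finite difference",
            "rel_step": rel_step,
            "step_factor": h,
            "t_end": t_end,
            "normalisation": "log-log (d ln output / d ln input); "
            "semi-relative fallback flagged per entry",
        },
    )


def rank_parameters(
    matrix: SensitivityMatrix, output: str = APOPTOSIS
) -> List[Tuple[str, float]]:
    """Inputs ordered by descending absolute sensitivity for one output.

    Ties are broken by lexicographic input id; NaN (failed) entries sort
    last.
    """
    if output not in matrix.values.columns:
        raise ConfigurationError(
            f"unknown output {output!r}; available: {list(matrix.values.columns)}"
        )
    col = matrix.values[output]
    entries = [
        (name, abs(float(col[name])))
        for name in matrix.values.index
    ]
    return sorted(
        entries, key=lambda kv: (math.isnan(kv[1]), -kv[1] if kv[1] == kv[1] else 0, kv[0])
    )
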