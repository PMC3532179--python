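"""In-silico experiment drivers: dose-response, pathway contributions,
parameter perturbation, and species modulation.

Every driver builds a fresh network per scenario (the bundled model is
never mutated), simulates it with shared settings, and reads the
cumulative apoptosis level at the end of the horizon.  Results carry
``to_frame`` / ``to_csv`` / ``summary`` helpers for tabular export.

The cross-talk decomposition runs the full model plus three exclusive
single-pathway models and attributes the residual

    crosstalk = total - (I_only + II_only + III_only)

to interactions among pathways; it is exact by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConfigurationError, SimulationError
from .model import (
    PATHWAYS,
    ModelConfig,
    REFERENCE_APOPTOSIS_LEVEL,
    apply_scaling,
    build_cisplatin_network,
    resolve_modulation_target,
)
from .network import ReactionNetwork
from .simulate import APOPTOSIS, SimulationSettings, Trajectory, simulate, write_csv


def _settings_dict(settings: SimulationSettings) -> dict:
    return {
        "t_end": settings.t_end,
        "rtol": settings.rtol,
        "atol": settings.atol,
        "n_points": settings.n_points,
        "method": settings.method,
    }


@dataclass(frozen=True)
class DoseResponseResult:
    """Apoptosis level at the end of the horizon per cisplatin dose."""

    concentrations: Tuple[float, ...]
    levels: Tuple[float, ...]
    settings: SimulationSettings

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cisplatin_concentration": self.concentrations,
                "apoptosis_level": self.levels,
            }
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        write_csv(self.to_frame(), path)

    def summary(self) -> dict:
        return {
            "experiment": "dose_response",
            "settings": _settings_dict(self.settings),
            "rows": [
                {"cisplatin_concentration": c, "apoptosis_level": l}
                for c, l in zip(self.concentrations, self.levels)
            ],
        }


@dataclass(frozen=True)
class ContributionResult:
    """Cross-talk decomposition of the total apoptosis level.

    ``exclusive[p]`` is the level with only pathway ``p`` active;
    ``crosstalk`` is the residual, so ``total == sum(exclusive.values())
    + crosstalk`` exactly.
    """

    total: float
    exclusive: Mapping[str, float]
    settings: SimulationSettings

    def __post_init__(self):
        object.__setattr__(self, "exclusive", dict(self.exclusive))

    @property
    def crosstalk(self) -> float:
        return self.total - sum(self.exclusive.values())

    @property
    def percentages(self) -> Dict[str, float]:
        """Each component as percent of total (all zero when total is 0)."""
        if self.total == 0:
            return {**{p: 0.0 for p in self.exclusive}, "crosstalk": 0.0, "total": 0.0}
        pct = {p: v / self.total * 100.0 for p, v in self.exclusive.items()}
        pct["crosstalk"] = self.crosstalk / self.total * 100.0
        pct["total"] = 100.0
        return pct

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages
        rows = [("total", self.total, pct["total"])]
        rows += [(f"pathway_{p}", v, pct[p]) for p, v in self.exclusive.items()]
        rows.append(("crosstalk", self.crosstalk, pct["crosstalk"]))
        return pd.DataFrame(rows, columns=["component", "apoptosis_level", "percent"])

    def to_csv(self, path: Union[str, Path]) -> None:
        write_csv(self.to_frame(), path)

    def summary(self) -> dict:
        return {
            "experiment": "pathway_contributions",
            "settings": _settings_dict(self.settings),
            "total": self.total,
            "exclusive": dict(self.exclusive),
            "crosstalk": self.crosstalk,
            "percentages": self.percentages,
        }


@dataclass(frozen=True)
class PerturbationResult:
    """Apoptosis levels after scaling single rate constants.

    ``rows`` are (parameter id, factor, level, percent change vs the
    simulated baseline of the same run).  The baseline row has id
    ``"baseline"`` and factor 1.
    """

    rows: Tuple[Tuple[str, float, float, float], ...]
    baseline: float
    settings: SimulationSettings

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.rows),
            columns=["parameter", "factor", "apoptosis_level", "percent_change"],
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        write_csv(self.to_frame(), path)

    def summary(self) -> dict:
        return {
            "experiment": "perturbation_scan",
            "settings": _settings_dict(self.settings),
            "baseline": self.baseline,
            "rows": [
                {
                    "parameter": p,
                    "factor": f,
                    "apoptosis_level": l,
                    "percent_change": c,
                }
                for p, f, l, c in self.rows
            ],
        }


@dataclass(frozen=True)
class ModulationResult:
    """Baseline vs modulated trajectories plus qualitative comparisons.

    ``comparisons[(target, factor)]`` maps readout name ("Apop", "Casp3*")
    to "greater" / "less" / "equal" at the end of the horizon.
    """

    baseline: Trajectory
    modulated: Mapping[Tuple[str, float], Trajectory]
    comparisons: Mapping[Tuple[str, float], Dict[str, str]]
    settings: SimulationSettings

    def __post_init__(self):
        object.__setattr__(self, "modulated", dict(self.modulated))
        object.__setattr__(self, "comparisons", dict(self.comparisons))

    def summary(self) -> dict:
        t_end = self.settings.t_end
        return {
            "experiment": "species_modulation",
            "settings": _settings_dict(self.settings),
            "baseline_apoptosis": self.baseline.value(APOPTOSIS, t_end),
            "cases": [
                {
                    "target": tgt,
                    "factor": f,
                    "apoptosis_level": traj.value(APOPTOSIS, t_end),
                    "comparison": self.comparisons[(tgt, f)],
                }
                for (tgt, f), traj in self.modulated.items()
            ],
        }


def _end_level(network: ReactionNetwork, settings: SimulationSettings) -> float:
    traj = simulate(network, settings)
    return traj.value(APOPTOSIS, settings.t_end)


def dose_response(
    concentrations: Sequence[float],
    settings: Optional[SimulationSettings] = None,
    config: Optional[ModelConfig] = None,
) -> DoseResponseResult:
    """One full-model simulation per cisplatin concentration, in input order."""
    settings = settings or SimulationSettings()
    base = config or ModelConfig()
    levels: List[float] = []
    for c in concentrations:
        cfg = ModelConfig(
            cisplatin_concentration=float(c),
            pathways_enabled=base.pathways_enabled,
            parameter_scales=base.parameter_scales,
            species_scales=base.species_scales,
        )
        try:
            levels.append(_end_level(build_cisplatin_network(cfg), settings))
        except SimulationError as exc:
            raise SimulationError(
                f"dose-response failed at concentration {c}: {exc}",
                time=exc.time,
                state=exc.state,
            ) from exc
    return DoseResponseResult(
        concentrations=tuple(float(c) for c in concentrations),
        levels=tuple(levels),
        settings=settings,
    )


def pathway_contributions(
    settings: Optional[SimulationSettings] = None,
    cisplatin: float = 1.0,
) -> ContributionResult:
    """Full model plus the three exclusive single-pathway knockouts."""
    settings = settings or SimulationSettings()
    total = _end_level(
        build_cisplatin_network(ModelConfig(cisplatin_concentration=cisplatin)),
        settings,
    )
    exclusive = {}
    for p in PATHWAYS:
        cfg = ModelConfig(
            cisplatin_concentration=cisplatin, pathways_enabled=frozenset({p})
        )
        exclusive[p] = _end_level(build_cisplatin_network(cfg), settings)
    return ContributionResult(total=total, exclusive=exclusive, settings=settings)


def perturbation_scan(
    parameter_ids: Sequence[str],
    factors: Sequence[float],
    settings: Optional[SimulationSettings] = None,
    config: Optional[ModelConfig] = None,
) -> PerturbationResult:
    """Cartesian product of parameter ids x scale factors, plus a baseline row.

    Unknown ids raise before any simulation runs.  Percent changes are
    computed against the simulated baseline of the same run, never a stored
    constant.
    """
    settings = settings or SimulationSettings()
    base_net = build_cisplatin_network(config)
    unknown = [p for p in parameter_ids if p not in base_net.parameters]
    if unknown:
        raise ConfigurationError(
            f"unknown rate constants {unknown}; valid ids: "
            f"{sorted(base_net.parameters.values)}"
        )
    baseline = _end_level(base_net, settings)
    rows: List[Tuple[str, float, float, float]] = [
        ("baseline", 1.0, baseline, 0.0)
    ]
    for pid in parameter_ids:
        for f in factors:
            if f == 1.0:
                rows.append((pid, 1.0, baseline, 0.0))
                continue
            net = apply_scaling(base_net, parameter_scales={pid: float(f)})
            level = _end_level(net, settings)
            change = (level - baseline) / baseline * 100.0 if baseline else float("nan")
            rows.append((pid, float(f), level, change))
    return PerturbationResult(rows=tuple(rows), baseline=baseline, settings=settings)


def species_modulation(
    spec: Sequence[Tuple[str, float]],
    settings: Optional[SimulationSettings] = None,
    config: Optional[ModelConfig] = None,
) -> ModulationResult:
    """Compare baseline against single-target up/down modulations.

    Targets with a nonzero baseline initial value are scaled directly;
    activated species (initial 0) are modulated through their
    activation-step rate constant (see
    :data:`cisapop.model.ACTIVATION_RATE_OF`).
    """
    settings = settings or SimulationSettings()
    base_net = build_cisplatin_network(config)
    baseline = simulate(base_net, settings)
    modulated = {}
    comparisons = {}
    readouts = (APOPTOSIS, "Casp3*")
    for target, factor in spec:
        kind, key = resolve_modulation_target(base_net, target)
        if factor == 1.0:
            traj = baseline
        elif kind == "parameter":
            traj = simulate(
                apply_scaling(base_net, parameter_scales={key: float(factor)}),
                settings,
            )
        else:
            traj = simulate(
                apply_scaling(base_net, species_scales={key: float(factor)}),
                settings,
            )
        modulated[(target, float(factor))] = traj
        comp = {}
        for name in readouts:
            a = traj.value(name, settings.t_end)
            b = baseline.value(name, settings.t_end)
            comp[name] = "greater" if a > b else ("less" if a < b else "equal")
        comparisons[(target, float(factor))] = comp
    return ModulationResult(
        baseline=baseline,
        modulated=modulated,
        comparisons=comparisons,
        settings=settings,
    )


def calibrate_horizon(
    target_level: float = REFERENCE_APOPTOSIS_LEVEL,
    settings: Optional[SimulationSettings] = None,
    config: Optional[ModelConfig] = None,
) -> float:
    """Time at which the full model's apoptosis level first reaches
    ``target_level``.

    The apoptosis readout is a nondecreasing accumulator, so a global
    rescaling of all rate constants is exactly a rescaling of time and the
    reported horizon is the single free convention in the model.  This
    root-finder pins it against a reference level (default: the bundled
    model's published full-dose readout).
    """
    settings = settings or SimulationSettings()
    net = build_cisplatin_network(config)
    _, sol = simulate(net, settings, dense=True)
    idx = net.species_index[APOPTOSIS]

    def f(t):
        return float(sol.sol(t)[idx]) - target_level

    hi = settings.t_end
    if f(hi) < 0:
        raise ConfigurationError(
            f"apoptosis level never reaches {target_level} within "
            f"t_end={settings.t_end}; increase the horizon"
        )
    return float(brentq(f, 0.0, hi, xtol=1e-12))


def write_summary(summary: dict, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
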