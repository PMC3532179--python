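"""The bundled cisplatin-induced apoptosis network.

The model couples three caspase-activating branches to a shared
caspase-9/-3/IAP core:

* **Pathway I** (death receptor): aquated cisplatin activates FasL, which
  binds and activates caspase-8; active caspase-8 activates caspase-3.
* **Pathway II** (mitochondrial), with two branches: **II-1** (DNA damage
  -> ATR -> p53 -> caspase-2/AIF release, and p53 -> Bax/Bak -> cytochrome
  c release) and **II-2** (mitochondrial ROS -> MPTP opening -> cytochrome
  c release); both converge on caspase-9 activation by cytosolic
  cytochrome c.
* **Pathway III** (ER stress): Ca2+ release -> calpain -> caspase-12 ->
  caspase-9.

Apoptosis (``Apop``) is a pure accumulator fed catalytically by active
caspase pairs (9*/3*, 8*/3*) and by caspase-2*/AIF.  All concentrations
and rate constants are dimensionless; the constant input species
``Cisplatin`` carries the dose (maximum 1).

Knockouts zero a pathway's constant input species (FasL; DNA and Mit; ER),
which removes exactly that pathway's signal source while leaving the
shared caspase core responsive to the remaining branches — the property
that makes the cross-talk decomposition in :mod:`cisapop.experiments`
meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Dict, FrozenSet, Iterable, Mapping

from .errors import ConfigurationError
from .netconfig import load_network
from .network import ReactionNetwork

PATHWAYS = ("I", "II", "III")

#: Constant input species that carry each pathway's signal source.
PATHWAY_INPUTS: Dict[str, tuple] = {
    "I": ("FasL",),
    "II": ("DNA", "Mit"),  # II-1 (DNA damage) and II-2 (ROS) branches
    "III": ("ER",),
}

#: Sub-branch switches for exploration (the contribution analysis always
#: treats II as the union of both branches).
SUBBRANCH_INPUTS: Dict[str, tuple] = {"II-1": ("DNA",), "II-2": ("Mit",)}

#: Activated species start at 0, so "scale the level of X*" is implemented
#: as scaling the rate constant of the step that produces X* (a sustained
#: change in its production flux rather than a vacuous initial-value scale).
ACTIVATION_RATE_OF: Dict[str, str] = {
    "Casp8*": "k34+",
    "Casp12*": "k6+",
    "P53*": "k17+",
    "Calpain*": "k4+",
    "Casp2*": "k19+",
    "FasL*": "k32+",
}

#: Reference full-dose apoptosis level of the bundled model, used to
#: calibrate the reporting horizon (see cisapop.experiments.calibrate_horizon).
REFERENCE_APOPTOSIS_LEVEL = 0.22512


@dataclass(frozen=True)
class ModelConfig:
    """Scenario description for building a (possibly modified) bundled model.

    ``pathways_enabled`` lists the active branches; disabling a pathway
    zeroes its constant input species.  ``parameter_scales`` /
    ``species_scales`` multiply rate constants / initial values after dose
    and knockouts are applied.
    """

    cisplatin_concentration: float = 1.0
    pathways_enabled: FrozenSet[str] = frozenset(PATHWAYS)
    parameter_scales: Mapping[str, float] = field(default_factory=dict)
    species_scales: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "pathways_enabled", frozenset(self.pathways_enabled))
        object.__setattr__(self, "parameter_scales", dict(self.parameter_scales))
        object.__setattr__(self, "species_scales", dict(self.species_scales))
        if self.cisplatin_concentration < 0:
            raise ConfigurationError("cisplatin_concentration must be >= 0")
        bad = self.pathways_enabled - set(PATHWAYS)
        if bad:
            raise ConfigurationError(
                f"unknown pathways {sorted(bad)}; valid: {PATHWAYS}"
            )
        if any(v <= 0 for v in self.parameter_scales.values()):
            raise ConfigurationError("parameter scales must be positive")
        if any(v < 0 for v in self.species_scales.values()):
            raise ConfigurationError("species scales must be nonnegative")


@lru_cache(maxsize=1)
def _bundled() -> ReactionNetwork:
    path = resources.files("cisapop").joinpath("data/cisplatin.yaml")
    return load_network(path.read_text())


def bundled_network() -> ReactionNetwork:
    """The unmodified bundled model (dose 1, all pathways active)."""
    return _bundled()


def build_cisplatin_network(config: ModelConfig | None = None) -> ReactionNetwork:
    """Instantiate the bundled network under a scenario configuration.

    Order of application: dose -> pathway knockouts -> parameter and
    species scalings.  The bundled network itself is never mutated.
    """
    config = config or ModelConfig()
    net = _bundled()
    net = net.with_initial_values({"Cisplatin": config.cisplatin_concentration})
    off = set(PATHWAYS) - config.pathways_enabled
    if off:
        net = apply_knockout(net, off)
    if config.parameter_scales or config.species_scales:
        net = apply_scaling(net, config.parameter_scales, config.species_scales)
    return net


def apply_knockout(network: ReactionNetwork, pathways_off: Iterable[str]) -> ReactionNetwork:
    """Copy of ``network`` with the given pathways' input species zeroed.

    ``pathways_off`` may contain "I", "II", "III" or the sub-branch labels
    "II-1" / "II-2".  The shared caspase core is untouched.
    """
    updates: Dict[str, float] = {}
    for p in pathways_off:
        inputs = PATHWAY_INPUTS.get(p) or SUBBRANCH_INPUTS.get(p)
        if inputs is None:
            valid = sorted(list(PATHWAY_INPUTS) + list(SUBBRANCH_INPUTS))
            raise ConfigurationError(f"unknown pathway {p!r}; valid: {valid}")
        updates.update({name: 0.0 for name in inputs})
    if not updates:
        return network
    return network.with_initial_values(updates)


def apply_scaling(
    network: ReactionNetwork,
    parameter_scales: Mapping[str, float] | None = None,
    species_scales: Mapping[str, float] | None = None,
) -> ReactionNetwork:
    """Copy with named rate constants / initial values multiplied by factors."""
    parameter_scales = parameter_scales or {}
    species_scales = species_scales or {}
    bad = set(parameter_scales) - set(network.parameters.values)
    if bad:
        raise ConfigurationError(
            f"unknown rate constants {sorted(bad)}; valid ids: "
            f"{sorted(network.parameters.values)}"
        )
    known = {s.name for s in network.species}
    bad = set(species_scales) - known
    if bad:
        raise ConfigurationError(
            f"unknown species {sorted(bad)}; valid names: {sorted(known)}"
        )
    out = network
    if parameter_scales:
        out = out.with_parameters(
            {k: out.parameters[k] * f for k, f in parameter_scales.items()}
        )
    if species_scales:
        out = out.with_initial_values(
            {
                n: out.species_by_name(n).initial_value * f
                for n, f in species_scales.items()
            }
        )
    return out


def resolve_modulation_target(network: ReactionNetwork, target: str):
    """Map a modulation target to the scaling that realises it.

    Returns ``("species", name)`` for species with a nonzero baseline
    initial value (scale the initial condition) and ``("parameter", kid)``
    for activated species that start at 0 (scale their activation-step rate
    constant, per :data:`ACTIVATION_RATE_OF`).
    """
    if target in ACTIVATION_RATE_OF:
        return "parameter", ACTIVATION_RATE_OF[target]
    for s in network.species:
        if s.name == target:
            if s.initial_value > 0 or s.role == "constant":
                return "species", target
            raise ConfigurationError(
                f"{target!r} starts at 0 and has no registered activation "
                f"step; modulatable activated species: "
                f"{sorted(ACTIVATION_RATE_OF)}"
            )
    raise ConfigurationError(f"unknown modulation target {target!r}")


def forward_rate_constants(network: ReactionNetwork | None = None) -> list:
    """Ids of the forward rate constants (k1+..k37+) in numeric order."""
    network = network or _bundled()
    fwd = [k for k in network.parameters.values if k.endswith("+")]
    return sorted(fwd, key=lambda k: int(k[1:-1]))
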