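"""Mass-action reaction networks and their compilation to ODE right-hand sides.

A :class:`ReactionNetwork` is an ordered list of species, a list of
mass-action reaction steps and a set of rate constants.  Species are either
*dynamic* (they get an ODE) or *constant* (fixed boundary inputs that may
only appear as catalysts).  Each reaction step distinguishes species that
are consumed, produced, or merely catalytic: catalysts enter the mass-action
rate law but receive no stoichiometric change.  The rate of a step is

    rate = k * prod(c_s ** nu_s  for s consumed) * prod(c_s for s catalyst)

where ``nu_s`` is the (positive integer) stoichiometry of a consumed
species.  :func:`build_rhs` compiles a network into a plain
``f(t, y) -> dy/dt`` closure over the dynamic-species state vector;
:func:`stoichiometric_matrix` and :func:`conservation_pools` expose the
usual structural analyses (net stoichiometry and the integer left null
space, i.e. conserved moieties).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Callable, Dict, FrozenSet, List, Mapping, Tuple

import numpy as np
import pandas as pd
import sympy

from .errors import NetworkError

SPECIES_ROLES = ("dynamic", "constant")
PATHWAY_TAGS = ("I", "II-1", "II-2", "III", "shared", "input")


@dataclass(frozen=True)
class SpeciesDef:
    """One chemical species: name, role and (dimensionless) initial value.

    ``pathway_tag`` records which signalling branch the species belongs to
    (purely annotational; knockouts key off species names, not tags).
    """

    name: str
    role: str = "dynamic"
    initial_value: float = 0.0
    pathway_tag: str = "shared"


@dataclass(frozen=True)
class ReactionStep:
    """A single irreversible mass-action event.

    ``consumed`` and ``produced`` map species names to positive integer
    stoichiometries; ``catalysts`` are species that multiply the rate law
    without being turned over.  Reversible bindings in the bundled model are
    encoded as two steps sharing a forward/reverse rate-constant pair.
    """

    id: str
    consumed: Mapping[str, int] = field(default_factory=dict)
    produced: Mapping[str, int] = field(default_factory=dict)
    catalysts: FrozenSet[str] = frozenset()
    rate_constant_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "consumed", dict(self.consumed))
        object.__setattr__(self, "produced", dict(self.produced))
        object.__setattr__(self, "catalysts", frozenset(self.catalysts))


@dataclass(frozen=True)
class RateConstantSet:
    """Named nonnegative rate constants (e.g. ``k7+`` = 10, ``k12-`` = 0.0035)."""

    values: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "values", dict(self.values))

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def __contains__(self, key: str) -> bool:
        return key in self.values


@dataclass(frozen=True)
class ReactionNetwork:
    """Species + reactions + rate constants, compilable to an ODE system.

    Species order is significant: the state vector of the compiled system is
    indexed by the dynamic species in declaration order.
    """

    species: Tuple[SpeciesDef, ...]
    reactions: Tuple[ReactionStep, ...]
    parameters: RateConstantSet

    def __post_init__(self):
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "reactions", tuple(self.reactions))

    @property
    def dynamic_species(self) -> List[SpeciesDef]:
        return [s for s in self.species if s.role == "dynamic"]

    @property
    def constant_species(self) -> List[SpeciesDef]:
        return [s for s in self.species if s.role == "constant"]

    @property
    def species_index(self) -> Dict[str, int]:
        """Name -> column index over dynamic species (declaration order)."""
        return {s.name: i for i, s in enumerate(self.dynamic_species)}

    def species_by_name(self, name: str) -> SpeciesDef:
        for s in self.species:
            if s.name == name:
                return s
        raise NetworkError(f"unknown species {name!r}")

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_value for s in self.dynamic_species], float)

    def with_initial_values(self, updates: Mapping[str, float]) -> "ReactionNetwork":
        """Copy of the network with some species' initial values replaced."""
        unknown = set(updates) - {s.name for s in self.species}
        if unknown:
            raise NetworkError(f"unknown species: {sorted(unknown)}")
        new = tuple(
            replace(s, initial_value=float(updates[s.name])) if s.name in updates else s
            for s in self.species
        )
        return replace(self, species=new)

    def with_parameters(self, updates: Mapping[str, float]) -> "ReactionNetwork":
        """Copy of the network with some rate constants replaced."""
        unknown = set(updates) - set(self.parameters.values)
        if unknown:
            raise NetworkError(f"unknown rate constants: {sorted(unknown)}")
        merged = dict(self.parameters.values)
        merged.update({k: float(v) for k, v in updates.items()})
        return replace(self, parameters=RateConstantSet(merged))

    def content_hash(self) -> str:
        """Stable hash of the full network definition (for provenance logs)."""
        payload = {
            "species": [
                (s.name, s.role, s.initial_value, s.pathway_tag) for s in self.species
            ],
            "reactions": [
                (
                    r.id,
                    sorted(r.consumed.items()),
                    sorted(r.produced.items()),
                    sorted(r.catalysts),
                    r.rate_constant_id,
                )
                for r in self.reactions
            ],
            "parameters": sorted(self.parameters.values.items()),
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def validate_network(network: ReactionNetwork) -> List[str]:
    """Check all structural invariants; return a list of violation messages.

    An empty list means the network is well formed.  Violations are data,
    not exceptions: callers that require validity should raise on a
    non-empty report (as :func:`build_rhs` does).
    """
    report: List[str] = []
    names = [s.name for s in network.species]
    seen = set()
    for n in names:
        if n in seen:
            report.append(f"species {n!r}: duplicate declaration")
        seen.add(n)
    roles = {s.name: s.role for s in network.species}
    for s in network.species:
        if s.role not in SPECIES_ROLES:
            report.append(f"species {s.name!r}: invalid role {s.role!r}")
        if not np.isfinite(s.initial_value) or s.initial_value < 0:
            report.append(
                f"species {s.name!r}: initial value {s.initial_value} is negative"
            )
    for kid, val in network.parameters.values.items():
        if not np.isfinite(val) or val < 0:
            report.append(f"rate constant {kid!r}: value {val} is negative")
    rids = set()
    for r in network.reactions:
        if r.id in rids:
            report.append(f"reaction {r.id!r}: duplicate id")
        rids.add(r.id)
        for group, members in (
            ("consumed", r.consumed),
            ("produced", r.produced),
            ("catalysts", r.catalysts),
        ):
            for name in members:
                if name not in roles:
                    report.append(
                        f"reaction {r.id!r}: {group} species {name!r} is not declared"
                    )
        for name, nu in list(r.consumed.items()) + list(r.produced.items()):
            if not (isinstance(nu, (int, np.integer)) and nu > 0):
                report.append(
                    f"reaction {r.id!r}: stoichiometry of {name!r} must be a "
                    f"positive integer, got {nu!r}"
                )
        overlap = set(r.consumed) & set(r.catalysts)
        if overlap:
            report.append(
                f"reaction {r.id!r}: species {sorted(overlap)} both consumed "
                "and catalytic"
            )
        for name in list(r.consumed) + list(r.produced):
            if roles.get(name) == "constant":
                report.append(
                    f"reaction {r.id!r}: constant species {name!r} may only "
                    "appear as a catalyst"
                )
        if r.rate_constant_id not in network.parameters:
            report.append(
                f"reaction {r.id!r}: rate constant {r.rate_constant_id!r} "
                "is not defined"
            )
    return report


def _require_valid(network: ReactionNetwork) -> None:
    report = validate_network(network)
    if report:
        raise NetworkError("invalid network:\n  " + "\n  ".join(report))


def build_rhs(network: ReactionNetwork) -> Callable[[float, np.ndarray], np.ndarray]:
    """Compile the network into a derivative function ``f(t, y) -> dy/dt``.

    The state vector ``y`` is indexed by dynamic species in declaration
    order.  Constant species contribute their fixed values as factors folded
    into each reaction's effective rate constant.  The returned closure is
    pure and deterministic.
    """
    _require_valid(network)
    index = network.species_index
    const_values = {s.name: s.initial_value for s in network.constant_species}
    n = len(index)

    # Per reaction: effective constant, [(state index, power)...], net stoich.
    compiled = []
    for r in network.reactions:
        k_eff = network.parameters[r.rate_constant_id]
        factors: List[Tuple[int, int]] = []
        for name, nu in r.consumed.items():
            factors.append((index[name], int(nu)))
        for name in sorted(r.catalysts):
            if name in const_values:
                k_eff *= const_values[name]
            else:
                factors.append((index[name], 1))
        net: Dict[int, int] = {}
        for name, nu in r.consumed.items():
            net[index[name]] = net.get(index[name], 0) - int(nu)
        for name, nu in r.produced.items():
            net[index[name]] = net.get(index[name], 0) + int(nu)
        compiled.append((k_eff, factors, sorted(net.items())))

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros(n)
        for k_eff, factors, net in compiled:
            rate = k_eff
            for i, p in factors:
                rate *= y[i] if p == 1 else y[i] ** p
            for i, s in net:
                dy[i] += s * rate
        return dy

    return rhs


def stoichiometric_matrix(network: ReactionNetwork) -> pd.DataFrame:
    """Net stoichiometry as an integer DataFrame (dynamic species x reactions).

    Entries are produced minus consumed stoichiometry; catalysts contribute
    zero by definition.
    """
    _require_valid(network)
    index = network.species_index
    dyn_names = [s.name for s in network.dynamic_species]
    mat = np.zeros((len(dyn_names), len(network.reactions)), dtype=int)
    for j, r in enumerate(network.reactions):
        for name, nu in r.consumed.items():
            mat[index[name], j] -= int(nu)
        for name, nu in r.produced.items():
            mat[index[name], j] += int(nu)
    return pd.DataFrame(mat, index=dyn_names, columns=[r.id for r in network.reactions])


def conservation_pools(network: ReactionNetwork) -> List[Dict[str, int]]:
    """Integer basis of conserved linear combinations of dynamic species.

    Computes the left null space of the stoichiometric matrix over the
    rationals and clears denominators, so each returned mapping
    ``{species: coefficient}`` satisfies ``sum(coeff * c_s) = const`` along
    any exact trajectory.  Signs are normalised so the first nonzero
    coefficient (in species declaration order) is positive.
    """
    S = stoichiometric_matrix(network)
    dyn_names = list(S.index)
    M = sympy.Matrix(S.to_numpy())
    basis = M.T.nullspace()
    pools: List[Dict[str, int]] = []
    for vec in basis:
        fracs = [Fraction(int(sympy.Rational(v).p), int(sympy.Rational(v).q)) for v in vec]
        denom_lcm = np.lcm.reduce([f.denominator for f in fracs]) if fracs else 1
        ints = [int(f * denom_lcm) for f in fracs]
        g = np.gcd.reduce([abs(v) for v in ints if v != 0] or [1])
        if g > 1:
            ints = [v // g for v in ints]
        first = next((v for v in ints if v != 0), 1)
        if first < 0:
            ints = [-v for v in ints]
        pools.append({n: v for n, v in zip(dyn_names, ints) if v != 0})
    return pools
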