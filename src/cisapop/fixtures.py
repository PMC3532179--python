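"""Random valid mass-action networks for property tests and examples."""

from __future__ import annotations

import numpy as np

from .network import RateConstantSet, ReactionNetwork, ReactionStep, SpeciesDef


def generate_fixture_network(
    seed: int, n_species: int = 5, n_reactions: int = 5
) -> ReactionNetwork:
    """A reproducible random network with unit stoichiometries.

    Species are named ``S0..S{n-1}`` with uniform initial values in
    [0, 2]; each reaction consumes 1-2 species, produces 1-2 species and
    may recruit one catalyst disjoint from its reactants; rate constants
    are uniform in [0.01, 10].  Identical seeds give identical networks.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if n_reactions < 0:
        raise ValueError("n_reactions must be >= 0")
    rng = np.random.default_rng(seed)
    names = [f"S{i}" for i in range(n_species)]
    species = tuple(
        SpeciesDef(name=n, role="dynamic", initial_value=float(rng.uniform(0, 2)))
        for n in names
    )
    reactions = []
    params = {}
    for j in range(n_reactions):
        kid = f"k{j}"
        params[kid] = float(rng.uniform(0.01, 10))
        n_cons = int(rng.integers(1, min(2, n_species) + 1))
        consumed = list(rng.choice(n_species, size=n_cons, replace=False))
        n_prod = int(rng.integers(1, min(2, n_species) + 1))
        produced = list(rng.choice(n_species, size=n_prod, replace=False))
        catalysts = []
        free = [i for i in range(n_species) if i not in consumed]
        if free and rng.random() < 0.5:
            catalysts = [int(rng.choice(free))]
        reactions.append(
            ReactionStep(
                id=f"r{j}",
                consumed={names[i]: 1 for i in consumed},
                produced={names[i]: 1 for i in produced},
                catalysts=frozenset(names[i] for i in catalysts),
                rate_constant_id=kid,
            )
        )
    return ReactionNetwork(
        species=species,
        reactions=tuple(reactions),
        parameters=RateConstantSet(params),
    )
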