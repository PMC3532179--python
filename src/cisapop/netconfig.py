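"""Read/write reaction networks as structured YAML config files.

The dialect is deliberately plain: one mapping per species, one per
reaction, and a flat ``parameters`` mapping, e.g. ::

    name: my-model
    species:
    - {name: A, role: dynamic, initial: 1.0, pathway: shared}
    reactions:
    - {id: k1+, rate: k1+, consumed: {A: 1}, produced: {B: 1}, catalysts: [E]}
    parameters:
      k1+: 0.5

``rate`` defaults to the reaction ``id``, which is the convention used by
the bundled model (one reaction per rate constant; reversible bindings are
split into ``k<i>+`` / ``k<i>-`` pairs).
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import yaml

from .errors import ConfigurationError
from .network import RateConstantSet, ReactionNetwork, ReactionStep, SpeciesDef


def network_from_dict(doc: dict) -> ReactionNetwork:
    try:
        species = tuple(
            SpeciesDef(
                name=str(s["name"]),
                role=str(s.get("role", "dynamic")),
                initial_value=float(s.get("initial", 0.0)),
                pathway_tag=str(s.get("pathway", "shared")),
            )
            for s in doc.get("species", [])
        )
        reactions = tuple(
            ReactionStep(
                id=str(r["id"]),
                consumed={str(k): int(v) for k, v in (r.get("consumed") or {}).items()},
                produced={str(k): int(v) for k, v in (r.get("produced") or {}).items()},
                catalysts=frozenset(str(c) for c in (r.get("catalysts") or [])),
                rate_constant_id=str(r.get("rate", r["id"])),
            )
            for r in doc.get("reactions", [])
        )
        parameters = RateConstantSet(
            {str(k): float(v) for k, v in (doc.get("parameters") or {}).items()}
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigurationError(f"malformed network config: {exc}") from exc
    return ReactionNetwork(species=species, reactions=reactions, parameters=parameters)


def network_to_dict(network: ReactionNetwork, name: str = "network") -> dict:
    return {
        "name": name,
        "species": [
            {
                "name": s.name,
                "role": s.role,
                "initial": float(s.initial_value),
                "pathway": s.pathway_tag,
            }
            for s in network.species
        ],
        "reactions": [
            {
                "id": r.id,
                "rate": r.rate_constant_id,
                "consumed": {k: int(v) for k, v in r.consumed.items()},
                "produced": {k: int(v) for k, v in r.produced.items()},
                "catalysts": sorted(r.catalysts),
            }
            for r in network.reactions
        ],
        "parameters": {k: float(v) for k, v in network.parameters.values.items()},
    }


def load_network(source: Union[str, Path]) -> ReactionNetwork:
    """Load a network from a YAML config file path or YAML text."""
    text = str(source)
    if "\n" not in text:
        try:
            path = Path(text)
            if path.exists():
                text = path.read_text()
        except OSError:
            pass
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ConfigurationError("network config must be a YAML mapping")
    return network_from_dict(doc)


def dump_network(network: ReactionNetwork, path: Union[str, Path, None] = None,
                 name: str = "network") -> str:
    """Serialise a network to YAML; write to ``path`` if given."""
    text = yaml.safe_dump(
        network_to_dict(network, name=name), sort_keys=False, width=100
    )
    if path is not None:
        Path(path).write_text(text)
    return text
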