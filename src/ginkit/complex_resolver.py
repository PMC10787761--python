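"""Recursive decomposition of BioPAX complexes into canonical leaf names.

A complex is named by its constituent leaf components: recursively expand
``component`` properties until no complexes remain, map each leaf to its
unified name, drop duplicates, sort ascending (plain byte order — locale
independent) and join with underscores.  Two complexes with the same leaf set
therefore share one name regardless of declaration order or nesting, which is
what lets identical complexes from different databases merge.

Non-protein members (small molecules, RNA) are kept as leaves under their own
unified IDs rather than dropped: discarding them would silently lose
interactions.  Homodimers collapse to a single name occurrence; stoichiometry
is ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .biopax_io import EntityRecord
from .diagnostics import Diagnostics
from .reaction_extract import Reaction

logger = logging.getLogger(__name__)


@dataclass
class ComplexResolution:
    complex_id: str
    leaf_components: tuple[str, ...]
    canonical_name: str


class ComplexCycleError(ValueError):
    """Raised when component references form a cycle."""


def canonical_complex_name(leaves) -> str:
    """Sorted (byte order) unique leaf names joined by underscores."""
    return "_".join(sorted(set(leaves)))


def resolve_complex(
    complex_id: str,
    entities: Mapping[str, EntityRecord] | Sequence[EntityRecord],
    id_map,
    diag: Diagnostics | None = None,
) -> ComplexResolution:
    """Depth-first expansion of one complex into its canonical resolution.

    ``id_map`` supplies unified leaf names via ``id_map.unified(entity_id)``
    (any object with that method, or a plain mapping).  A leaf with no
    resolvable name becomes ``UNMAPPED:<entity_id>`` and is counted; cyclic
    component references raise :class:`ComplexCycleError` naming the cycle.
    """
    if not isinstance(entities, Mapping):
        entities = {e.entity_id: e for e in entities}

    def leaf_name(entity_id: str) -> str:
        if hasattr(id_map, "unified"):
            name = id_map.unified(entity_id)
        else:
            name = entities_leaf_lookup(id_map, entity_id)
        if name is None:
            if diag is not None:
                diag.count("complex_leaf_unmapped")
            logger.warning("complex %s: unmapped leaf %s", complex_id, entity_id)
            return f"UNMAPPED:{entity_id}"
        return name

    leaves: list[str] = []

    def expand(entity_id: str, stack: tuple[str, ...]) -> None:
        if entity_id in stack:
            cycle = " -> ".join(stack + (entity_id,))
            raise ComplexCycleError(f"cyclic complex components: {cycle}")
        entity = entities.get(entity_id)
        if entity is not None and entity.biopax_class == "Complex":
            for component in entity.prop("component"):
                expand(component, stack + (entity_id,))
        else:
            leaves.append(leaf_name(entity_id))

    root = entities.get(complex_id)
    if root is None or root.biopax_class != "Complex":
        raise ValueError(f"{complex_id!r} does not name a Complex")
    for component in root.prop("component"):
        expand(component, (complex_id,))

    unique_leaves = tuple(sorted(set(leaves)))
    return ComplexResolution(
        complex_id=complex_id,
        leaf_components=unique_leaves,
        canonical_name=canonical_complex_name(unique_leaves),
    )


def entities_leaf_lookup(id_map: Mapping, entity_id: str):
    value = id_map.get(entity_id)
    if isinstance(value, tuple):
        return value[0]
    return value


def resolve_all_complexes(
    entities: Sequence[EntityRecord],
    id_map,
    diag: Diagnostics | None = None,
) -> dict[str, ComplexResolution]:
    """Resolution for every Complex individual in the document."""
    by_id = {e.entity_id: e for e in entities}
    return {
        e.entity_id: resolve_complex(e.entity_id, by_id, id_map, diag)
        for e in entities
        if e.biopax_class == "Complex"
    }


def rewrite_complex_ids(
    reactions: Sequence[Reaction],
    resolutions: Mapping[str, ComplexResolution],
    complex_ids: frozenset[str] | set[str] | None = None,
) -> list[Reaction]:
    """Replace complex entity IDs in reactions by their canonical names.

    When ``complex_ids`` is given, a participant known to be a complex but
    lacking a resolution is an error listing the offending reactions.
    """
    if complex_ids is not None:
        missing = set(complex_ids) - set(resolutions)
        offenders = sorted(
            r.reaction_id for r in reactions if r.participants() & missing
        )
        if offenders:
            raise ValueError(
                f"unresolved complexes in reactions: {', '.join(offenders)}"
            )

    def rename(entity_id: str) -> str:
        resolution = resolutions.get(entity_id)
        return resolution.canonical_name if resolution is not None else entity_id

    rewritten = []
    for reaction in reactions:
        rewritten.append(
            replace(
                reaction,
                substrates=tuple(sorted({rename(s) for s in reaction.substrates})),
                products=tuple(sorted({rename(p) for p in reaction.products})),
                controllers=tuple(
                    sorted({(rename(c), sign) for c, sign in reaction.controllers})
                ),
                cofactors=tuple(sorted({rename(c) for c in reaction.cofactors})),
            )
        )
    return rewritten


def resolutions_to_rows(resolutions: Mapping[str, ComplexResolution]) -> list[dict]:
    return [
        {
            "complex_id": res.complex_id,
            "canonical_name": res.canonical_name,
            "leaf_components": ";".join(res.leaf_components),
        }
        for res in resolutions.values()
    ]
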