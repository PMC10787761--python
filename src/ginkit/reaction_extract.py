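"""Extract biochemical reactions and their controllers from parsed BioPAX.

Reactions come from six conversion classes (TransportWithBiochemicalReaction,
Transport, BiochemicalReaction, ComplexAssembly, Degradation, Conversion);
controllers come from Catalysis, Control and Modulation individuals whose
``controlled`` points at an extracted reaction.  Stoichiometry is discarded:
participants are sets.  A Catalysis without an explicit controlType is
activating (that is its BioPAX definition); a bare Control/Modulation without
controlType has unknown sign.  Controls whose target is not an extracted
reaction (e.g. a Control controlling another Control) are logged, not chained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .biopax_io import EntityRecord
from .diagnostics import Diagnostics

logger = logging.getLogger(__name__)

REACTION_CLASSES = (
    "TransportWithBiochemicalReaction",
    "Transport",
    "BiochemicalReaction",
    "ComplexAssembly",
    "Degradation",
    "Conversion",
)
CONTROL_CLASSES = ("Catalysis", "Control", "Modulation")

ACTIVATION = "activation"
INHIBITION = "inhibition"
UNKNOWN = "unknown"


@dataclass
class Reaction:
    """A directed biochemical event with controllers carrying a sign."""

    reaction_id: str
    reaction_class: str
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    controllers: tuple[tuple[str, str], ...] = ()
    cofactors: tuple[str, ...] = ()
    source_db: str = ""

    def participants(self) -> set[str]:
        return (
            set(self.substrates)
            | set(self.products)
            | {name for name, _ in self.controllers}
            | set(self.cofactors)
        )


def _unique(values: Iterable[str]) -> tuple[str, ...]:
    """Collapse multiplicity to a set, deterministically ordered."""
    return tuple(sorted(set(values)))


def extract_reactions(
    entities: Sequence[EntityRecord],
    source_db: str,
    expand_reversible: bool = False,
    diag: Diagnostics | None = None,
) -> list[Reaction]:
    """Turn every individual of the six conversion classes into a Reaction.

    ``left`` feeds substrates; ``right`` and ``product`` feed products.
    Reactions with neither substrates nor products are dropped and counted.
    With ``expand_reversible``, a conversion marked REVERSIBLE additionally
    emits the mirror reaction under ``<id>__rev`` (its own intermediate).
    """
    reactions: list[Reaction] = []
    dropped = 0
    for entity in entities:
        if entity.biopax_class not in REACTION_CLASSES:
            continue
        substrates = _unique(entity.prop("left"))
        products = _unique(entity.prop("right") + entity.prop("product"))
        if not substrates and not products:
            dropped += 1
            logger.info("dropping reaction %s: no participants", entity.entity_id)
            continue
        reactions.append(
            Reaction(
                reaction_id=entity.entity_id,
                reaction_class=entity.biopax_class,
                substrates=substrates,
                products=products,
                source_db=source_db,
            )
        )
        direction = entity.first("conversionDirection") or ""
        if expand_reversible and direction.strip().upper() == "REVERSIBLE":
            reactions.append(
                Reaction(
                    reaction_id=f"{entity.entity_id}__rev",
                    reaction_class=entity.biopax_class,
                    substrates=products,
                    products=substrates,
                    source_db=source_db,
                )
            )
    if diag is not None:
        diag.count("reactions_extracted", len(reactions))
        if dropped:
            diag.count("reactions_dropped_no_participants", dropped)
    return reactions


def control_sign(biopax_class: str, control_type: str | None) -> str:
    """Map a BioPAX controlType to an edge sign.

    ``ACTIVATION*`` → activation, ``INHIBITION*`` → inhibition; with no
    controlType, Catalysis is activating by definition, other controls are
    unknown.
    """
    if control_type:
        upper = control_type.strip().upper()
        if upper.startswith("ACTIVATION"):
            return ACTIVATION
        if upper.startswith("INHIBITION"):
            return INHIBITION
    return ACTIVATION if biopax_class == "Catalysis" else UNKNOWN


def attach_controls(
    entities: Sequence[EntityRecord],
    reactions: Sequence[Reaction],
    diag: Diagnostics | None = None,
) -> list[Reaction]:
    """Link Catalysis/Control/Modulation controllers to their reactions.

    Substrates and products are never altered.  Catalysis cofactors are
    recorded separately; controls targeting anything that is not an extracted
    reaction are counted and skipped.
    """
    by_reaction = {r.reaction_id: r for r in reactions}
    extra_controllers: dict[str, list[tuple[str, str]]] = {}
    extra_cofactors: dict[str, list[str]] = {}
    unattached = 0

    for entity in entities:
        if entity.biopax_class not in CONTROL_CLASSES:
            continue
        sign = control_sign(entity.biopax_class, entity.first("controlType"))
        controllers = entity.prop("controller")
        for target in entity.prop("controlled"):
            if target not in by_reaction:
                unattached += 1
                logger.info(
                    "%s %s controls non-reaction %s; not attached",
                    entity.biopax_class, entity.entity_id, target,
                )
                continue
            extra_controllers.setdefault(target, []).extend(
                (controller, sign) for controller in controllers
            )
            if entity.biopax_class == "Catalysis":
                extra_cofactors.setdefault(target, []).extend(entity.prop("cofactor"))

    result = []
    for reaction in reactions:
        added = extra_controllers.get(reaction.reaction_id, [])
        cofactors = extra_cofactors.get(reaction.reaction_id, [])
        if added or cofactors:
            merged = sorted(set(reaction.controllers) | set(added))
            reaction = replace(
                reaction,
                controllers=tuple(merged),
                cofactors=_unique(tuple(reaction.cofactors) + tuple(cofactors)),
            )
        result.append(reaction)

    if diag is not None:
        attached = sum(len(v) for v in extra_controllers.values())
        diag.count("controllers_attached", attached)
        if unattached:
            diag.count("controls_targeting_non_reaction", unattached)
    return result


def reactions_to_rows(reactions: Iterable[Reaction]) -> list[dict]:
    """Rows for the reaction-table TSV export."""
    return [
        {
            "reaction_id": r.reaction_id,
            "reaction_class": r.reaction_class,
            "substrates": ";".join(r.substrates),
            "products": ";".join(r.products),
            "controllers": ";".join(f"{name}|{sign}" for name, sign in r.controllers),
            "cofactors": ";".join(r.cofactors),
            "source_db": r.source_db,
        }
        for r in reactions
    ]
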