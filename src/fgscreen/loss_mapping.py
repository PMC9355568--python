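"""Mapping gene-loss states and shared inactivating mutations onto the tree.

Gene loss is treated as irreversible (Dollo parsimony): a lost reading
frame is never regained, so the minimum-event reconstruction places one
loss on the stem of every maximal clade whose informative leaves are all
lost.  Leaves with missing status (assembly gaps) are uninformative —
they neither create nor destroy events.

Independently, identical lesions (same kind at the same codon) observed
in all informative leaves of a clade are assigned to that clade's stem
branch as likely ancestral events; near-matches one codon apart are
reported separately and never merged.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import dendropy

from .genescan import MutationEvent
from .phylo import (
    check_species_in_tree,
    maximal_uniform_clades,
    node_label,
)

__all__ = [
    "LossEvent",
    "AncestralMutation",
    "dollo_count",
    "shared_mutations",
]


@dataclass(frozen=True)
class LossEvent:
    """One inferred loss on a tree branch (identified by its child node)."""

    branch: str
    descendant_lost_species: frozenset[str]


def dollo_count(
    tree: dendropy.Tree, statuses: dict[str, str]
) -> tuple[int, list[LossEvent]]:
    """Minimum number of independent loss events under Dollo parsimony.

    ``statuses`` maps leaf names to ``lost`` / ``intact`` / ``missing``;
    leaves absent from the mapping count as missing.  Events are placed on
    the deepest branches consistent with the minimum: the stems of maximal
    clades whose informative leaves are all lost.  Rejects input with no
    informative leaf.
    """
    known = {s for s, st in statuses.items() if st in ("lost", "intact")}
    check_species_in_tree(tree, set(statuses))
    if not known:
        raise ValueError("all leaves have missing status; count undefined")

    clades = maximal_uniform_clades(
        tree,
        in_state=lambda s: statuses.get(s) == "lost",
        uninformative=lambda s: statuses.get(s, "missing") == "missing",
    )
    events = sorted(
        (
            LossEvent(branch=node_label(node), descendant_lost_species=leaves)
            for node, leaves in clades
        ),
        key=lambda e: min(e.descendant_lost_species),
    )
    return len(events), events


@dataclass(frozen=True)
class AncestralMutation:
    """A lesion assigned to an ancestral branch (or leaf-private)."""

    kind: str
    codon_start: int
    branch: str
    species: frozenset[str]

    @property
    def ancestral(self) -> bool:
        return len(self.species) > 1


def shared_mutations(
    mutations: dict[str, list[MutationEvent]],
    tree: dendropy.Tree,
    missing: set[str] | frozenset[str] = frozenset(),
) -> tuple[list[AncestralMutation], list[tuple]]:
    """Assign identical lesions shared across species to ancestral branches.

    A lesion key is ``(kind, codon_start)``.  For each key, the maximal
    clades in which every informative leaf carries the lesion get one
    assignment on their stem; carriers outside such clades stay
    leaf-private.  Species in ``missing`` are uninformative.

    Returns ``(assignments, possibly_shared)`` where ``possibly_shared``
    lists cross-species same-kind lesions exactly one codon apart, as
    ``(kind, codon_a, codon_b, species_a, species_b)`` — reported for
    manual review, never auto-merged.
    """
    check_species_in_tree(tree, set(mutations))
    carriers: dict[tuple[str, int], set[str]] = {}
    for sp, muts in mutations.items():
        for m in muts:
            carriers.setdefault(m.key, set()).add(sp)

    with_data = set(mutations) - set(missing)

    def uninformative(sp: str) -> bool:
        return sp not in with_data

    assignments: list[AncestralMutation] = []
    for (kind, codon), who in sorted(carriers.items()):
        clades = maximal_uniform_clades(
            tree, in_state=lambda s: s in who, uninformative=uninformative
        )
        for node, leaves in clades:
            assignments.append(
                AncestralMutation(
                    kind=kind,
                    codon_start=codon,
                    branch=node_label(node),
                    species=leaves,
                )
            )

    possibly: list[tuple] = []
    keys = sorted(carriers)
    for (ka, ca), (kb, cb) in combinations(keys, 2):
        if ka == kb and abs(ca - cb) == 1:
            for sa in sorted(carriers[(ka, ca)]):
                for sb in sorted(carriers[(kb, cb)]):
                    if sa != sb:
                        possibly.append((ka, ca, cb, sa, sb))
    return assignments, possibly
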