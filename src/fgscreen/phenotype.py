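"""Phenotype assignment: low-/high-acuity grouping and foreground lineages.

Species are labelled foreground (poor vision) either by thresholding
visual acuity — the ability to resolve static spatial detail, in cycles
per degree — or by a molecular signature: having lost at least a minimum
number of marker genes (e.g. genes annotated with 'visual perception').
Foreground species are then partitioned into independent lineages, taken
to be the maximal monophyletic clades whose leaves are all foreground:
each such clade is compatible with a single ancestral transition to the
poor-vision state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import pandas as pd

from .phylo import check_species_in_tree, maximal_uniform_clades

__all__ = [
    "AcuityTable",
    "PhenotypeAssignment",
    "classify_by_acuity",
    "classify_by_signature",
    "partition_lineages",
]

ACUITY_SOURCES = ("behavioral", "anatomical", "proxy_relative", "assumed_zero")

FOREGROUND = "foreground"
BACKGROUND = "background"
EXCLUDED = "excluded"


@dataclass
class AcuityTable:
    """Per-species visual acuity (cycles/degree) with measurement source.

    Functionally blind species without measurements must be explicitly
    flagged ``assumed_zero`` (with va = 0) rather than inferred; species
    with no value and no flag are excluded from classification.
    """

    table: pd.DataFrame  # columns: species_id, va, source

    def __post_init__(self) -> None:
        req = {"species_id", "va", "source"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"acuity table missing columns: {sorted(missing)}")
        t = self.table
        known = t["va"].notna()
        if (t.loc[known, "va"] < 0).any():
            bad = t.loc[known & (t["va"] < 0), "species_id"].tolist()
            raise ValueError(f"negative visual acuity for {bad}")
        az = t["source"] == "assumed_zero"
        if (t.loc[az, "va"].fillna(0) != 0).any():
            raise ValueError("assumed_zero entries must have va = 0")
        if t["species_id"].duplicated().any():
            dups = t.loc[t["species_id"].duplicated(), "species_id"].tolist()
            raise ValueError(f"duplicate species in acuity table: {dups}")

    @property
    def species(self) -> list[str]:
        return self.table["species_id"].tolist()


@dataclass
class PhenotypeAssignment:
    """Foreground/background labels plus the foreground lineage partition."""

    labels: dict[str, str]
    lineages: list[frozenset[str]] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def foreground(self) -> frozenset[str]:
        return frozenset(s for s, l in self.labels.items() if l == FOREGROUND)

    @property
    def background(self) -> frozenset[str]:
        return frozenset(s for s, l in self.labels.items() if l == BACKGROUND)

    def with_lineages(self, tree: dendropy.Tree) -> "PhenotypeAssignment":
        """Return a copy with the lineage partition computed on ``tree``."""
        return PhenotypeAssignment(
            labels=dict(self.labels),
            lineages=partition_lineages(tree, self.foreground),
            provenance=dict(self.provenance),
        )


def classify_by_acuity(
    acuity: AcuityTable, threshold: float = 1.0
) -> PhenotypeAssignment:
    """Foreground iff visual acuity < ``threshold`` (default 1 cyc/deg).

    Species without a value and without the ``assumed_zero`` flag are
    excluded.  Monotone in the threshold: raising it can only add
    foreground species.
    """
    if threshold <= 0:
        raise ValueError("acuity threshold must be positive")
    labels: dict[str, str] = {}
    for row in acuity.table.itertuples(index=False):
        if pd.isna(row.va) and row.source != "assumed_zero":
            labels[row.species_id] = EXCLUDED
        else:
            va = 0.0 if pd.isna(row.va) else float(row.va)
            labels[row.species_id] = FOREGROUND if va < threshold else BACKGROUND
    return PhenotypeAssignment(
        labels=labels, provenance={"method": "acuity", "threshold": threshold}
    )


def classify_by_signature(
    status: pd.DataFrame,
    marker_genes: set[str],
    min_lost: int = 5,
) -> PhenotypeAssignment:
    """Foreground iff the species has lost >= ``min_lost`` marker genes.

    ``status`` is a gene x species frame of status strings; only the
    ``lost`` state counts toward the signature.
    """
    if not marker_genes:
        raise ValueError("marker gene set is empty")
    missing = sorted(marker_genes - set(status.index))
    if missing:
        raise ValueError(f"marker genes absent from status matrix: {missing}")
    sub = status.loc[sorted(marker_genes)]
    n_lost = (sub == "lost").sum(axis=0)
    labels = {
        sp: (FOREGROUND if n_lost[sp] >= min_lost else BACKGROUND)
        for sp in status.columns
    }
    return PhenotypeAssignment(
        labels=labels,
        provenance={
            "method": "signature",
            "min_lost": min_lost,
            "n_markers": len(marker_genes),
        },
    )


def partition_lineages(
    tree: dendropy.Tree, foreground: frozenset[str] | set[str]
) -> list[frozenset[str]]:
    """Partition foreground species into maximal all-foreground clades.

    Each returned set is the leaf set of a clade containing only
    foreground species and not nested inside a larger such clade.  The
    union is exactly ``foreground``; the sets are pairwise disjoint.
    Sorted by smallest member for reproducible output.
    """
    foreground = frozenset(foreground)
    check_species_in_tree(tree, foreground)
    clades = maximal_uniform_clades(tree, lambda s: s in foreground)
    return sorted((leaves for _, leaves in clades), key=lambda s: min(s))
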