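"""Synthetic phylogenomic data with the structure the screen assumes.

The generator produces an ultrametric pure-birth species tree, selects a
small number of disjoint clades as poor-vision foreground lineages,
samples a visual-acuity covariate that separates the groups, and evolves
per-gene inactivating-mutation histories: after the trait is lost at a
foreground lineage's stem, associated genes accumulate lesions as a
Poisson process at an elevated rate (relaxed selection) on every branch
within the lineage, on top of a low background noise rate that applies to
all genes on all branches.  Mutations arising on internal branches are
inherited by all descendant species, so shared ancestral lesions arise
naturally.  Lesion lists can be rendered into codon alignments carrying
exactly the implanted mutations, giving the mutation detector an
end-to-end ground-truth oracle.

Branch lengths are in arbitrary time units with the tree scaled to a
root-to-tip height of ``tree_height`` (default 100, roughly the age of
the placental radiation in millions of years), so mutation rates are
per-lineage per time unit.

All randomness flows from one seed through named substreams (tree,
phenotype, acuity, one per gene), so any single gene is reproducible in
isolation.
"""

from __future__ import annotations

import random
import zlib
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .genescan import (
    GAP,
    STOP_CODONS,
    CodingAlignment,
    MutationEvent,
    MutationKind,
    percent_intact,
)
from .phenotype import (
    AcuityTable,
    BACKGROUND,
    FOREGROUND,
    PhenotypeAssignment,
    partition_lineages,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_tree",
    "assign_phenotype",
    "simulate_gene",
    "emit_alignments",
    "simulate_dataset",
    "default_exon_bounds",
    "matrix_from_mutations",
]

DEFAULT_KIND_MIX = {
    MutationKind.FRAMESHIFT_DELETION: 0.3,
    MutationKind.FRAMESHIFT_INSERTION: 0.2,
    MutationKind.PREMATURE_STOP: 0.35,
    MutationKind.SPLICE_SITE: 0.1,
    MutationKind.EXON_DELETION: 0.05,
}

#: default foreground lineage sizes mirror the screen's study design:
#: ten poor-vision species in seven lineages (four singleton subterranean
#: lineages, one three-species bat clade, one singleton rodent, one
#: two-species rodent clade)
DEFAULT_LINEAGE_SIZES = (3, 2, 1, 1, 1, 1, 1)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic benchmark."""

    n_species: int = 49
    birth_rate: float = 1.0
    tree_height: float = 100.0
    n_fg_lineages: int = 7
    lineage_sizes: tuple[int, ...] | None = DEFAULT_LINEAGE_SIZES
    fg_min_age_frac: float = 0.2
    n_genes: int = 2000
    n_associated: int = 20
    lambda_fg: float = 0.13
    lambda_bg: float = 2e-4
    cds_len: int = 300
    n_exons: int = 8
    kind_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_KIND_MIX)
    )
    va_fg_range: tuple[float, float] = (0.05, 0.9)
    va_bg_range: tuple[float, float] = (1.1, 60.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_associated > self.n_genes:
            raise ValueError("n_associated cannot exceed n_genes")
        if self.lambda_bg > self.lambda_fg:
            raise ValueError("lambda_bg must not exceed lambda_fg")
        if abs(sum(self.kind_mix.values()) - 1.0) > 1e-9:
            raise ValueError("kind_mix must sum to 1")
        if self.lineage_sizes is not None and (
            len(self.lineage_sizes) != self.n_fg_lineages
        ):
            raise ValueError("lineage_sizes length must equal n_fg_lineages")


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    config: SimConfig
    tree: dendropy.Tree
    assignment: PhenotypeAssignment
    acuity: AcuityTable
    associated_genes: frozenset[str]
    mutations: dict[str, dict[str, list[MutationEvent]]]  # gene -> species -> events


def _substream(seed: int, *names: str) -> np.random.Generator:
    # zlib.crc32 is stable across processes, unlike builtin str hashing
    ss = np.random.SeedSequence(
        seed, spawn_key=tuple(zlib.crc32(n.encode()) for n in names)
    )
    return np.random.default_rng(ss)


def simulate_tree(
    n_species: int,
    birth_rate: float = 1.0,
    seed: int = 0,
    height: float = 100.0,
    attempt: int = 0,
) -> dendropy.Tree:
    """Ultrametric pure-birth (Yule) tree scaled to the given root height.

    Leaves are labelled ``sp01 .. spNN``; reproducible per seed.
    ``attempt`` selects an independent draw under the same seed (used to
    condition the tree on admitting a requested lineage configuration).
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = random.Random(
        int(_substream(seed, "tree", str(attempt)).integers(2**31))
    )
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=rng,
    )
    tree.seed_node.edge.length = None
    width = len(str(n_species))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{i:0{width}d}"
    # the process stops at the n-th birth, leaving the last cherry with
    # zero-length tips; continue the clock by one exponential waiting time
    # so all pendant edges are strictly positive (tree stays ultrametric)
    hang = rng.expovariate(n_species * birth_rate)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length += hang
    depth = max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )
    scale = height / depth
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    return tree


def assign_phenotype(
    tree: dendropy.Tree,
    n_fg_lineages: int,
    seed: int = 0,
    lineage_sizes: tuple[int, ...] | None = None,
    va_fg_range: tuple[float, float] = (0.05, 0.9),
    va_bg_range: tuple[float, float] = (1.1, 60.0),
    min_age_frac: float = 0.25,
    max_tries: int = 500,
) -> tuple[PhenotypeAssignment, AcuityTable]:
    """Pick disjoint foreground clades and sample a consistent acuity table.

    Only clades whose stem originates at least ``min_age_frac`` of the
    tree height above the present are eligible, emulating anciently
    trait-lost lineages: relaxed selection must have had time to leave
    lesions, so very recent tip lineages are not candidate foregrounds.

    Foreground acuity is sampled uniformly below 1 and background acuity
    log-uniformly above 1, so thresholding the table at 1 recovers the
    intended labels exactly, and the lineage partition of the result has
    exactly ``n_fg_lineages`` sets (verified; infeasible requests raise).
    """
    rng = _substream(seed, "phenotype")
    height = max(
        lf.distance_from_root() for lf in tree.leaf_node_iter()
    )
    min_age = min_age_frac * height
    # age of a lineage = height above the present of its stem's origin
    nodes = [
        nd
        for nd in tree.preorder_node_iter()
        if nd.parent_node is not None
        and height - nd.parent_node.distance_from_root() >= min_age
    ]
    by_size: dict[int, list] = {}
    for nd in nodes:
        by_size.setdefault(len(nd.leaf_nodes()), []).append(nd)
    sizes = (
        tuple(lineage_sizes)
        if lineage_sizes is not None
        else tuple([1] * n_fg_lineages)
    )
    if len(sizes) != n_fg_lineages:
        raise ValueError("lineage_sizes length must equal n_fg_lineages")

    leaves_all = [lf.taxon.label for lf in tree.leaf_node_iter()]
    for _ in range(max_tries):
        chosen: list[frozenset[str]] = []
        taken: set[str] = set()
        ok = True
        for size in sorted(sizes, reverse=True):
            cands = [
                nd
                for nd in by_size.get(size, [])
                if not (set(lf.taxon.label for lf in nd.leaf_iter()) & taken)
            ]
            if not cands:
                ok = False
                break
            nd = cands[int(rng.integers(len(cands)))]
            leaves = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            chosen.append(leaves)
            taken |= leaves
        if not ok:
            continue
        fg = frozenset(taken)
        lineages = partition_lineages(tree, fg)
        if len(lineages) == n_fg_lineages:
            break
    else:
        raise ValueError(
            f"could not place {n_fg_lineages} disjoint foreground lineages "
            f"of sizes {sizes} on this tree"
        )

    arng = _substream(seed, "acuity")
    lo_f, hi_f = va_fg_range
    lo_b, hi_b = va_bg_range
    rows = []
    labels = {}
    for sp in leaves_all:
        if sp in fg:
            va = float(arng.uniform(lo_f, hi_f))
            labels[sp] = FOREGROUND
        else:
            va = float(np.exp(arng.uniform(np.log(lo_b), np.log(hi_b))))
            labels[sp] = BACKGROUND
        rows.append({"species_id": sp, "va": va, "source": "behavioral"})
    acuity = AcuityTable(pd.DataFrame(rows))
    assignment = PhenotypeAssignment(
        labels=labels,
        lineages=sorted(lineages, key=lambda s: min(s)),
        provenance={"method": "simulated", "n_fg_lineages": n_fg_lineages},
    )
    return assignment, acuity


def default_exon_bounds(n_codons: int, n_exons: int) -> list[tuple[int, int]]:
    """Split ``n_codons`` into ``n_exons`` near-equal half-open intervals."""
    if n_exons < 1 or n_codons < 2 * n_exons:
        raise ValueError("exons must hold at least 2 codons each")
    edges = np.linspace(0, n_codons, n_exons + 1).round().astype(int)
    return [(int(edges[i]), int(edges[i + 1])) for i in range(n_exons)]


def _foreground_nodes(
    tree: dendropy.Tree, lineages: list[frozenset[str]]
) -> set[dendropy.Node]:
    """Nodes whose edge lies within a foreground lineage, stem included."""
    out: set[dendropy.Node] = set()
    taxa = tree.taxon_namespace
    for lin in lineages:
        if len(lin) == 1:
            mrca = tree.find_node_with_taxon_label(next(iter(lin)))
        else:
            mrca = tree.mrca(taxa=[taxa.get_taxon(s) for s in sorted(lin)])
        out.add(mrca)
        for nd in mrca.preorder_iter():
            out.add(nd)
    return out


def _draw_position(
    rng: np.random.Generator,
    kind: str,
    bounds: list[tuple[int, int]],
    n_codons: int,
    used: set[int],
    max_tries: int = 200,
) -> tuple[int, int] | None:
    """Codon span for a lesion, avoiding already-used codons."""
    for _ in range(max_tries):
        if kind == MutationKind.EXON_DELETION:
            s, e = bounds[int(rng.integers(len(bounds)))]
            span = range(s, e)
        elif kind == MutationKind.SPLICE_SITE:
            b = int(rng.integers(len(bounds) - 1))
            donor = bool(rng.integers(2))
            anchor = bounds[b][1] - 1 if donor else bounds[b + 1][0]
            s, e = anchor, anchor + 1
            span = range(s, e)
        else:
            s = int(rng.integers(1, n_codons - 1))
            e = s + 1
            span = range(s, e)
        if not (set(span) & used):
            used.update(span)
            return s, e
    return None


def simulate_gene(
    tree: dendropy.Tree,
    assignment: PhenotypeAssignment,
    associated: bool,
    cfg: SimConfig,
    seed: int,
) -> dict[str, list[MutationEvent]]:
    """Evolve one gene's inactivating mutations along the tree.

    Each branch receives ``Poisson(rate * length)`` lesions, where the
    rate is ``lambda_bg`` everywhere plus ``lambda_fg`` on branches within
    foreground lineages (stem included) when the gene is associated.
    Lesions on internal branches are inherited by every descendant
    species.  Lesion codons are unique within the gene so implanted sets
    round-trip exactly through alignment rendering and detection.
    """
    rng = _substream(cfg.seed, "gene", str(seed))
    bounds = default_exon_bounds(cfg.cds_len, cfg.n_exons)
    fg_nodes = (
        _foreground_nodes(tree, assignment.lineages) if associated else set()
    )
    kinds = list(cfg.kind_mix)
    probs = np.array([cfg.kind_mix[k] for k in kinds])
    used: set[int] = set()
    per_species: dict[str, list[MutationEvent]] = {
        lf.taxon.label: [] for lf in tree.leaf_node_iter()
    }

    def walk(node: dendropy.Node, inherited: list[MutationEvent]) -> None:
        own = list(inherited)
        if node.parent_node is not None:
            rate = cfg.lambda_bg + (
                cfg.lambda_fg if node in fg_nodes else 0.0
            )
            n_mut = int(rng.poisson(rate * (node.edge.length or 0.0)))
            for _ in range(n_mut):
                kind = kinds[int(rng.choice(len(kinds), p=probs))]
                pos = _draw_position(rng, kind, bounds, cfg.cds_len, used)
                if pos is None:
                    continue
                own.append(
                    MutationEvent(
                        kind=kind, codon_start=pos[0], codon_end=pos[1]
                    )
                )
        if node.is_leaf():
            per_species[node.taxon.label] = sorted(own)
        else:
            for ch in node.child_nodes():
                walk(ch, own)

    walk(tree.seed_node, [])
    return per_species


_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


def emit_alignments(
    mutations: dict[str, list[MutationEvent]],
    cds_len: int,
    seed: int = 0,
    n_exons: int = 8,
    gene_id: str = "gene",
    absent_codons: dict[str, list[tuple[int, int]]] | None = None,
) -> dict[str, CodingAlignment]:
    """Render codon alignments carrying exactly the listed lesions.

    A random reference CDS (ATG start, no internal stops, single terminal
    stop) is generated once; each species' query starts as a perfect copy
    and the lesions are implanted: stop codons substituted in place,
    frameshifts as 1-2 nt gaps inside the lesion codon, splice lesions as
    non-canonical dinucleotides in the sidecar, exon deletions as all-gap
    exons.  ``absent_codons`` spans are written as ``N`` (assembly gaps).
    """
    rng = _substream(seed, "emit", gene_id)
    bounds = default_exon_bounds(cds_len, n_exons)
    ref = (
        "ATG"
        + "".join(
            _SENSE_CODONS[int(rng.integers(len(_SENSE_CODONS)))]
            for _ in range(cds_len - 2)
        )
        + "TAA"
    )
    starts = {s for s, _ in bounds}
    out: dict[str, CodingAlignment] = {}
    for sp in sorted(mutations):
        ref_cols = list(ref)
        qry_cols = list(ref)
        splice = [["GT", "AG"] for _ in range(n_exons - 1)]
        for m in sorted(mutations[sp], key=lambda m: -m.codon_start):
            c = m.codon_start
            if m.kind == MutationKind.PREMATURE_STOP:
                stop = sorted(STOP_CODONS)[int(rng.integers(3))]
                qry_cols[3 * c : 3 * c + 3] = list(stop)
            elif m.kind == MutationKind.FRAMESHIFT_DELETION:
                d = int(rng.integers(1, 3))
                for k in range(3 - d, 3):
                    qry_cols[3 * c + k] = GAP
            elif m.kind == MutationKind.FRAMESHIFT_INSERTION:
                d = int(rng.integers(1, 3))
                ins = "".join(
                    "ACGT"[int(rng.integers(4))] for _ in range(d)
                )
                # insert after the codon's first base
                ref_cols.insert(3 * c + 1, GAP * d)
                qry_cols.insert(3 * c + 1, ins)
            elif m.kind == MutationKind.SPLICE_SITE:
                if c in starts and c != 0:
                    b = [s for s, _ in bounds].index(c) - 1
                    splice[b][1] = "CC"  # broken acceptor
                else:
                    b = [e for _, e in bounds].index(c + 1)
                    splice[b][0] = "CT"  # broken donor
            elif m.kind == MutationKind.EXON_DELETION:
                for k in range(3 * m.codon_start, 3 * m.codon_end):
                    qry_cols[k] = GAP
            elif m.kind == MutationKind.GENE_DELETION:
                for k in range(3 * cds_len):
                    qry_cols[k] = GAP
        if absent_codons and sp in absent_codons:
            for s, e in absent_codons[sp]:
                for k in range(3 * s, 3 * e):
                    if qry_cols[k] != GAP:
                        qry_cols[k] = "N"
        out[sp] = CodingAlignment(
            gene_id=gene_id,
            species_id=sp,
            ref_aln="".join(ref_cols),
            query_aln="".join(qry_cols),
            exon_bounds=bounds,
            splice_sites=[tuple(p) for p in splice],
        )
    return out


def matrix_from_mutations(
    truth: SimTruth,
) -> pd.DataFrame:
    """Gene x species %intact matrix computed from the implanted lesions."""
    species = sorted(
        lf.taxon.label for lf in truth.tree.leaf_node_iter()
    )
    genes = sorted(truth.mutations)
    data = np.empty((len(genes), len(species)))
    L = truth.config.cds_len
    for gi, g in enumerate(genes):
        per_sp = truth.mutations[g]
        for si, sp in enumerate(species):
            data[gi, si] = percent_intact(per_sp.get(sp, []), L)
    return pd.DataFrame(data, index=genes, columns=species)


def simulate_dataset(cfg: SimConfig) -> SimTruth:
    """Generate a full benchmark dataset: tree, phenotype, gene histories.

    The tree draw is conditioned on admitting the requested foreground
    lineage configuration: if the clade sizes/ages cannot be placed, a
    fresh tree is drawn (up to 20 attempts) before giving up.
    """
    last_err: Exception | None = None
    for attempt in range(20):
        tree = simulate_tree(
            cfg.n_species, cfg.birth_rate, cfg.seed, cfg.tree_height, attempt
        )
        try:
            assignment, acuity = assign_phenotype(
                tree,
                cfg.n_fg_lineages,
                seed=cfg.seed,
                lineage_sizes=cfg.lineage_sizes,
                va_fg_range=cfg.va_fg_range,
                va_bg_range=cfg.va_bg_range,
                min_age_frac=cfg.fg_min_age_frac,
            )
            break
        except ValueError as err:
            last_err = err
    else:
        raise ValueError(
            f"no tree admitting the lineage configuration in 20 draws: "
            f"{last_err}"
        )
    width = len(str(cfg.n_genes))
    genes = [f"g{i:0{width}d}" for i in range(cfg.n_genes)]
    pick = _substream(cfg.seed, "associated")
    associated = frozenset(
        genes[i]
        for i in pick.choice(cfg.n_genes, size=cfg.n_associated, replace=False)
    )
    mutations = {
        g: simulate_gene(tree, assignment, g in associated, cfg, i)
        for i, g in enumerate(genes)
    }
    return SimTruth(
        config=cfg,
        tree=tree,
        assignment=assignment,
        acuity=acuity,
        associated_genes=associated,
        mutations=mutations,
    )
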