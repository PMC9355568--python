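"""Readers and writers for the screen's file formats.

Formats: Newick (species trees), TSV (%intact matrices, acuity tables,
mutation and result tables; ``NA`` encodes missing), GMT (gene sets),
FASTA pairs plus an exon sidecar TSV (codon alignments).  Species names
are normalised identically everywhere (spaces to underscores, case
preserved); label mismatches between tables and tree are reported, never
silently dropped.  All writers are deterministic: fixed column order,
floats at six significant digits, no timestamps.
"""

from __future__ import annotations

import logging
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .genescan import CodingAlignment, IntactnessRecord, MutationEvent
from .phenotype import AcuityTable
from .screen import ScreenResult, results_frame

__all__ = [
    "normalize_species",
    "read_newick",
    "write_newick",
    "read_matrix",
    "write_matrix",
    "read_acuity",
    "write_acuity",
    "read_gmt",
    "write_gmt",
    "read_alignments",
    "write_alignments",
    "write_mutations",
    "read_mutations",
    "write_intactness",
    "write_screen_results",
    "check_labels",
]

log = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


def normalize_species(name: str) -> str:
    return name.strip().replace(" ", "_")


def _fmt(x) -> str:
    if isinstance(x, float):
        if np.isnan(x):
            return "NA"
        return FLOAT_FMT % x
    return str(x)


# ---------------------------------------------------------------- trees


def read_newick(path: str | Path, zero_length_epsilon: float = 1e-8) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths.

    Duplicate leaf labels or missing internal/leaf branch lengths are
    rejected; zero-length branches are replaced by a small epsilon with a
    warning so the Brownian covariance stays positive definite.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.utility.error.DataParseError as err:
        # dendropy reports line/column in its message
        raise ValueError(f"{path}: {err}") from None
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    dups = sorted({l for l in labels if labels.count(l) > 1})
    if dups:
        raise ValueError(f"{path}: duplicate leaf labels: {dups}")
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.edge.length is None:
            raise ValueError(
                f"{path}: missing branch length above "
                f"{node.taxon.label if node.is_leaf() else 'an internal node'}"
            )
        if node.edge.length < 0:
            raise ValueError(f"{path}: negative branch length")
        if node.edge.length == 0:
            log.warning(
                "%s: zero-length branch replaced by epsilon %g",
                path,
                zero_length_epsilon,
            )
            node.edge.length = zero_length_epsilon
    for lf in tree.leaf_node_iter():
        lf.taxon.label = normalize_species(lf.taxon.label)
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(
        tree.as_string(
            schema="newick", unquoted_underscores=True, real_value_format_specifier=".6g"
        )
    )


# --------------------------------------------------------------- tables


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Gene x species %intact matrix from TSV; 'NA' is missing."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.columns = [normalize_species(c) for c in df.columns]
    try:
        df = df.astype(float)
    except ValueError as err:
        raise ValueError(f"{path}: non-numeric %intact value ({err})") from None
    bad = df.where((df < 0) | (df > 100)).stack()
    if len(bad):
        (gene, sp) = bad.index[0]
        raise ValueError(
            f"{path}: %intact out of [0, 100] at gene {gene}, species {sp}: "
            f"{bad.iloc[0]}"
        )
    return df


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(
        path, sep="\t", float_format=FLOAT_FMT, na_rep="NA", index_label="gene_id"
    )


def read_acuity(path: str | Path) -> AcuityTable:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    df["species_id"] = df["species_id"].map(normalize_species)
    return AcuityTable(df)


def write_acuity(acuity: AcuityTable, path: str | Path) -> None:
    acuity.table.to_csv(
        path, sep="\t", float_format=FLOAT_FMT, na_rep="NA", index=False
    )


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: GMT line needs name, description, genes")
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = ".") -> None:
    lines = [
        "\t".join([name, description, *sorted(genes)])
        for name, genes in sorted(sets.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def check_labels(tree: dendropy.Tree, species: list[str]) -> None:
    """Cross-validate table species against tree leaves with a full report."""
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    table = set(species)
    only_table = sorted(table - leaves)
    only_tree = sorted(leaves - table)
    if only_table:
        raise ValueError(
            f"species in tables but not in tree: {only_table}; "
            f"tree-only species: {only_tree}"
        )


# ----------------------------------------------------------- alignments


def write_alignments(
    alignments: dict[str, CodingAlignment],
    fasta_path: str | Path,
    sidecar_path: str | Path,
) -> None:
    """FASTA pairs (reference then query per species) + exon sidecar TSV.

    Sidecar columns: gene_id, exon_index, codon_start, codon_end, donor,
    acceptor (query dinucleotides flanking the boundary *after* the exon;
    last exon has NA).
    """
    recs = []
    side = []
    for sp in sorted(alignments):
        aln = alignments[sp]
        recs.append(f">{aln.gene_id}|ref|{sp}\n{aln.ref_aln}")
        recs.append(f">{aln.gene_id}|query|{sp}\n{aln.query_aln}")
        for i, (s, e) in enumerate(aln.exon_bounds):
            donor, acc = ("NA", "NA")
            if i < len(aln.exon_bounds) - 1 and aln.splice_sites:
                donor, acc = aln.splice_sites[i]
            side.append(
                dict(
                    gene_id=aln.gene_id,
                    species_id=sp,
                    exon_index=i,
                    codon_start=s,
                    codon_end=e,
                    donor=donor,
                    acceptor=acc,
                )
            )
    Path(fasta_path).write_text("\n".join(recs) + "\n")
    pd.DataFrame(side).to_csv(sidecar_path, sep="\t", index=False)


def read_alignments(
    fasta_path: str | Path, sidecar_path: str | Path
) -> dict[tuple[str, str], CodingAlignment]:
    """Inverse of :func:`write_alignments`, keyed by (gene, species)."""
    from Bio import SeqIO

    seqs: dict[tuple[str, str, str], str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        gene, role, sp = rec.id.split("|", 2)
        seqs[(gene, role, normalize_species(sp))] = str(rec.seq)
    side = pd.read_csv(sidecar_path, sep="\t", na_values=["NA"], dtype={"donor": str, "acceptor": str})
    side["species_id"] = side["species_id"].map(normalize_species)
    out: dict[tuple[str, str], CodingAlignment] = {}
    for (gene, sp), grp in side.groupby(["gene_id", "species_id"], sort=True):
        grp = grp.sort_values("exon_index")
        bounds = [
            (int(r.codon_start), int(r.codon_end))
            for r in grp.itertuples(index=False)
        ]
        splice = [
            (str(r.donor), str(r.acceptor))
            for r in grp.itertuples(index=False)
            if isinstance(r.donor, str)
        ]
        out[(gene, sp)] = CodingAlignment(
            gene_id=gene,
            species_id=sp,
            ref_aln=seqs[(gene, "ref", sp)],
            query_aln=seqs[(gene, "query", sp)],
            exon_bounds=bounds,
            splice_sites=splice,
        )
    return out


# -------------------------------------------------------------- results


def write_mutations(
    mutations: list[MutationEvent], path: str | Path
) -> None:
    rows = [
        dict(
            gene_id=m.gene_id,
            species_id=m.species_id,
            kind=m.kind,
            codon_start=m.codon_start,
            codon_end=m.codon_end,
        )
        for m in sorted(
            mutations, key=lambda m: (m.gene_id, m.species_id, m.codon_start, m.kind)
        )
    ]
    pd.DataFrame(
        rows,
        columns=["gene_id", "species_id", "kind", "codon_start", "codon_end"],
    ).to_csv(path, sep="\t", index=False)


def read_mutations(path: str | Path) -> list[MutationEvent]:
    df = pd.read_csv(path, sep="\t")
    return [
        MutationEvent(
            gene_id=r.gene_id,
            species_id=normalize_species(r.species_id),
            kind=r.kind,
            codon_start=int(r.codon_start),
            codon_end=int(r.codon_end),
        )
        for r in df.itertuples(index=False)
    ]


def write_intactness(
    records: list[IntactnessRecord], path: str | Path
) -> None:
    rows = [
        dict(
            gene_id=r.gene_id,
            species_id=r.species_id,
            percent_intact=_fmt(r.percent_intact),
            present_fraction=_fmt(r.present_fraction),
            status=r.status,
        )
        for r in sorted(records, key=lambda r: (r.gene_id, r.species_id))
    ]
    pd.DataFrame(
        rows,
        columns=["gene_id", "species_id", "percent_intact", "present_fraction", "status"],
    ).to_csv(path, sep="\t", index=False)


def write_screen_results(results: list[ScreenResult], path: str | Path) -> None:
    df = results_frame(results)
    df["candidate"] = df["candidate"].map({True: "true", False: "false"})
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
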