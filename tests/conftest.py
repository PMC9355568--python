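"""Shared fixtures: tiny trees and alignment builders."""

from __future__ import annotations

import dendropy
import numpy as np
import pytest

from fgscreen.genescan import CodingAlignment, STOP_CODONS


def make_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )


@pytest.fixture
def balanced4() -> dendropy.Tree:
    """((A:1,B:1):1,(C:1,D:1):1) — the hand-checkable PGLS tree."""
    return make_tree("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def star6() -> dendropy.Tree:
    """Six equidistant leaves: GLS must collapse to OLS."""
    return make_tree("(A:1,B:1,C:1,D:1,E:1,F:1);")


def make_cds(n_codons: int, seed: int = 0) -> str:
    """Random CDS with ATG start, no internal stop, TAA terminal."""
    rng = np.random.default_rng(seed)
    sense = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in STOP_CODONS
    ]
    body = "".join(
        sense[i] for i in rng.integers(len(sense), size=n_codons - 2)
    )
    return "ATG" + body + "TAA"


def make_alignment(
    n_codons: int = 300,
    query_edits: dict[int, str] | None = None,
    exon_bounds: list[tuple[int, int]] | None = None,
    splice_sites: list[tuple[str, str]] | None = None,
    seed: int = 0,
    gene: str = "g",
    species: str = "s",
) -> CodingAlignment:
    """Reference-identical alignment with optional per-codon query edits.

    ``query_edits[i]`` replaces query codon ``i`` (use '-' characters for
    deletions, lowercase handled upstream); edits never change alignment
    length, so insertions are built by tests directly when needed.
    """
    ref = make_cds(n_codons, seed)
    qry = list(ref)
    for i, repl in (query_edits or {}).items():
        assert len(repl) == 3
        qry[3 * i : 3 * i + 3] = list(repl)
    bounds = exon_bounds or [(0, n_codons)]
    return CodingAlignment(
        gene_id=gene,
        species_id=species,
        ref_aln=ref,
        query_aln="".join(qry),
        exon_bounds=bounds,
        splice_sites=splice_sites
        or [("GT", "AG")] * (len(bounds) - 1),
    )
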