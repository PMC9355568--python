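"""Generate the default synthetic benchmark dataset.

49 species, 7 poor-vision foreground lineages (10 species), 2,000 genes
of which 20 are associated with the phenotype (lesions accrue at the
relaxed-selection rate on foreground branches).  Writes the tree, acuity
table, %intact matrix, mutation table and ground truth under
results/benchmark/.
"""

from pathlib import Path

import pandas as pd

from fgscreen import io
from fgscreen.genescan import MutationEvent
from fgscreen.simulate import SimConfig, matrix_from_mutations, simulate_dataset

OUT = Path(__file__).resolve().parent.parent / "results" / "benchmark"


def main(seed: int = 0) -> None:
    cfg = SimConfig(seed=seed)
    truth = simulate_dataset(cfg)
    OUT.mkdir(parents=True, exist_ok=True)

    io.write_newick(truth.tree, OUT / "tree.nwk")
    io.write_acuity(truth.acuity, OUT / "acuity.tsv")
    io.write_matrix(matrix_from_mutations(truth), OUT / "matrix.tsv")
    pd.DataFrame(
        {
            "gene_id": sorted(truth.mutations),
            "associated": [
                str(g in truth.associated_genes).lower()
                for g in sorted(truth.mutations)
            ],
        }
    ).to_csv(OUT / "truth.tsv", sep="\t", index=False)
    muts = [
        MutationEvent(
            kind=m.kind,
            codon_start=m.codon_start,
            codon_end=m.codon_end,
            gene_id=g,
            species_id=sp,
        )
        for g, per_sp in truth.mutations.items()
        for sp, ms in per_sp.items()
        for m in ms
    ]
    io.write_mutations(muts, OUT / "mutations.tsv")

    fg = sorted(truth.assignment.foreground)
    print(f"wrote benchmark dataset to {OUT}")
    print(
        f"  {cfg.n_species} species, {len(fg)} foreground in "
        f"{len(truth.assignment.lineages)} lineages: {fg}"
    )
    print(
        f"  {cfg.n_genes} genes ({cfg.n_associated} associated), "
        f"{len(muts)} implanted lesions"
    )


if __name__ == "__main__":
    main()
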