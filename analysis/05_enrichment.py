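"""Gene-set over-representation of the screen candidates.

Builds a marker set from the simulated truth (the associated genes play
the role of an annotated 'visual perception' set), tests the candidate
list for over-representation with the one-sided Fisher's exact test and
BH correction, and writes results/enrichment/enrichment.tsv.
"""

from pathlib import Path

import pandas as pd

from fgscreen.enrichment import fisher_enrichment

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "enrichment"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    screen = pd.read_csv(BASE / "screen" / "results.tsv", sep="\t")
    truth = pd.read_csv(BASE / "benchmark" / "truth.tsv", sep="\t")

    universe = set(screen.gene_id)
    candidates = set(
        screen.loc[
            screen.candidate.map(lambda v: str(v).lower() == "true"),
            "gene_id",
        ]
    )
    assoc = set(
        truth.loc[
            truth.associated.map(lambda v: str(v).lower() == "true"),
            "gene_id",
        ]
    ) & universe
    decoy = set(sorted(universe - assoc)[:50])
    sets = {"associated_markers": assoc, "decoy_markers": decoy}

    rows = fisher_enrichment(candidates, universe, sets, sided="greater")
    pd.DataFrame(
        [
            {
                "set_name": r.set_name,
                "overlap": r.overlap,
                "set_size": r.set_size,
                "n_candidates": r.n_candidates,
                "n_universe": r.n_universe,
                "odds_ratio": r.odds_ratio,
                "p_value": r.p_value,
                "q_value": r.q_value,
            }
            for r in rows
        ]
    ).to_csv(OUT / "enrichment.tsv", sep="\t", index=False)
    for r in rows:
        print(
            f"{r.set_name}: overlap {r.overlap}/{r.set_size}, "
            f"p = {r.p_value:.3g}, q = {r.q_value:.3g}"
        )


if __name__ == "__main__":
    main()
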