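"""Gene-set over-representation of screen candidates.

For each user-supplied gene set, a 2x2 table of candidate membership
against set membership over the post-filter gene universe is tested with
Fisher's exact test (one-sided over-representation by default; two-sided
available), and p-values are Benjamini-Hochberg corrected across sets.
No ontology is bundled: sets arrive in GMT files, so results never depend
on a database version.
"""

from __future__ import annotations

from dataclasses import dataclass

import scipy.stats

from .screen import bh_adjust

__all__ = ["EnrichmentRow", "fisher_enrichment"]


@dataclass(frozen=True)
class EnrichmentRow:
    set_name: str
    overlap: int  # k: candidates in the set
    set_size: int  # K: set members in the universe
    n_candidates: int  # n
    n_universe: int  # N
    odds_ratio: float
    p_value: float
    q_value: float


def fisher_enrichment(
    candidates: set[str],
    universe: set[str],
    gene_sets: dict[str, set[str]],
    sided: str = "greater",
) -> list[EnrichmentRow]:
    """Fisher's-exact over-representation of candidates in each gene set.

    ``sided='greater'`` gives the hypergeometric upper tail
    P(overlap >= k); ``'two-sided'`` the standard two-sided Fisher p.
    Candidates must be a subset of the universe; sets are intersected
    with the universe.  Rows are BH-corrected across sets and returned
    sorted by (q, p, set name).
    """
    if not universe:
        raise ValueError("empty gene universe")
    if sided not in ("greater", "two-sided"):
        raise ValueError(f"unknown sidedness {sided!r}")
    extra = candidates - universe
    if extra:
        raise ValueError(
            f"candidates outside the universe: {sorted(extra)[:5]}"
        )
    N = len(universe)
    n = len(candidates)
    rows = []
    for name in sorted(gene_sets):
        members = gene_sets[name] & universe
        K = len(members)
        k = len(candidates & members)
        table = [[k, n - k], [K - k, N - n - K + k]]
        if sided == "greater":
            # upper tail of Hypergeom(N, K, n) at k
            p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n))
        else:
            _, p = scipy.stats.fisher_exact(table, alternative="two-sided")
        num = k * (N - n - K + k)
        den = (n - k) * (K - k)
        odds = num / den if den else float("inf") if num else float("nan")
        rows.append((name, k, K, float(odds), min(float(p), 1.0)))
    q = bh_adjust([r[4] for r in rows])
    out = [
        EnrichmentRow(
            set_name=name,
            overlap=k,
            set_size=K,
            n_candidates=n,
            n_universe=N,
            odds_ratio=odds,
            p_value=p,
            q_value=float(qi),
        )
        for (name, k, K, odds, p), qi in zip(rows, q)
    ]
    out.sort(key=lambda r: (r.q_value, r.p_value, r.set_name))
    return out
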