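"""The forward-genomics association screen.

For every gene, the %intact value per species is regressed on the binary
foreground (poor-vision) indicator with phylogenetic generalized least
squares: the error covariance is the Brownian-motion matrix V whose (i, j)
entry is the shared root-to-tip path length of species i and j, so
phylogenetic relatedness cannot masquerade as convergence.  Genes are
ranked by Benjamini-Hochberg-corrected one-sided p-values (alternative:
foreground depresses %intact) and candidates must additionally be lost in
a minimum number of independent foreground lineages.

The same machinery runs the control screen with a substituted foreground
set (e.g. the high-acuity sister species of the original foreground).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .phenotype import BACKGROUND, FOREGROUND, PhenotypeAssignment
from .phylo import brownian_covariance

__all__ = [
    "ScreenResult",
    "filter_genes",
    "pgls_fit",
    "bh_adjust",
    "convergent_loss_count",
    "run_screen",
    "control_screen",
    "loss_statuses",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenResult:
    """Per-gene association result."""

    gene_id: str
    n_species_used: int
    slope: float
    t_stat: float
    p_value: float
    q_value: float
    n_lost_lineages: int
    candidate: bool
    degenerate: bool = False


def filter_genes(
    matrix: pd.DataFrame, assignment: PhenotypeAssignment
) -> pd.DataFrame:
    """Drop genes unusable by the association test.

    Removes genes with missing %intact for more than 50% of foreground or
    more than 50% of background species, and genes whose non-missing
    values are all identical (no variation, no association possible).
    Gene order is preserved.
    """
    fg = sorted(assignment.foreground & set(matrix.columns))
    bg = sorted(assignment.background & set(matrix.columns))
    if not fg or not bg:
        raise ValueError("both phenotype classes must be present in the matrix")
    fg_missing = matrix[fg].isna().mean(axis=1) > 0.5
    bg_missing = matrix[bg].isna().mean(axis=1) > 0.5
    constant = matrix.nunique(axis=1, dropna=True) <= 1
    keep = ~(fg_missing | bg_missing | constant)
    dropped = int((~keep).sum())
    if dropped:
        log.info(
            "filter_genes: dropped %d of %d genes (%d missing-heavy, %d constant)",
            dropped,
            len(matrix),
            int((fg_missing | bg_missing).sum()),
            int((constant & ~(fg_missing | bg_missing)).sum()),
        )
    out = matrix.loc[keep]
    if out.empty:
        log.warning("filter_genes: no genes retained")
    return out


_DEGENERATE = (0.0, 0.0, 1.0)


def _gls(
    y: np.ndarray, x: np.ndarray, cho: tuple, one_sided: bool = True
) -> tuple[float, float, float]:
    """Closed-form GLS of y on [1, x] given a Cholesky factor of V."""
    n = y.size
    X = np.column_stack([np.ones(n), x])
    Vi_X = scipy.linalg.cho_solve(cho, X)
    Vi_y = scipy.linalg.cho_solve(cho, y)
    XtViX = X.T @ Vi_X
    try:
        XtViX_inv = np.linalg.inv(XtViX)
    except np.linalg.LinAlgError:
        return _DEGENERATE
    beta = XtViX_inv @ (X.T @ Vi_y)
    resid = y - X @ beta
    df = n - 2
    if df <= 0:
        return _DEGENERATE
    s2 = float(resid @ scipy.linalg.cho_solve(cho, resid)) / df
    var_b = s2 * XtViX_inv[1, 1]
    if var_b <= 0:
        return _DEGENERATE
    t = float(beta[1] / np.sqrt(var_b))
    if one_sided:
        p = float(scipy.stats.t.cdf(t, df))  # alternative: slope < 0
    else:
        p = float(2 * scipy.stats.t.sf(abs(t), df))
    return float(beta[1]), t, p


def pgls_fit(
    y: pd.Series | dict[str, float],
    x: pd.Series | dict[str, float],
    tree: dendropy.Tree,
    *,
    one_sided: bool = True,
) -> tuple[float, float, float]:
    """PGLS of a trait on a predictor under Brownian-motion covariance.

    ``y`` and ``x`` are keyed by species; the tree is restricted to the
    species with non-missing ``y``.  Returns ``(slope, t, p)`` where the
    one-sided p tests slope < 0.  Degenerate inputs (constant response,
    singular covariance) yield ``(0, 0, 1)`` rather than an exception.
    """
    y = pd.Series(dict(y)) if not isinstance(y, pd.Series) else y
    x = pd.Series(dict(x)) if not isinstance(x, pd.Series) else x
    species = sorted(y.dropna().index)
    if len(species) < 3:
        raise ValueError("PGLS needs at least 3 species with data")
    yv = y[species].to_numpy(dtype=float)
    xv = x[species].to_numpy(dtype=float)
    if np.unique(xv).size < 2:
        raise ValueError("both phenotype classes must be represented")
    if np.unique(yv).size < 2:
        return _DEGENERATE
    V = brownian_covariance(tree, species)
    try:
        cho = scipy.linalg.cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return _DEGENERATE
    return _gls(yv, xv, cho, one_sided=one_sided)


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def loss_statuses(
    values: pd.Series, loss_thr: float = 60.0
) -> dict[str, str]:
    """Map %intact values to lost/intact/missing for one gene.

    Only ``lost`` (below ``loss_thr``) matters to convergence counting;
    missing values are uninformative.
    """
    out = {}
    for sp, v in values.items():
        if pd.isna(v):
            out[sp] = "missing"
        else:
            out[sp] = "lost" if v < loss_thr else "intact"
    return out


def convergent_loss_count(
    statuses: dict[str, str], lineages: list[frozenset[str]]
) -> int:
    """Number of foreground lineages containing at least one lost species."""
    return sum(
        any(statuses.get(sp) == "lost" for sp in lin) for lin in lineages
    )


class _CovarianceCache:
    """Cholesky factors of the pruned Brownian covariance, keyed by the
    species subset actually used — genes sharing a missingness pattern
    share one factorisation."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self._cache: dict[tuple[str, ...], tuple] = {}

    def get(self, species: tuple[str, ...]):
        if species not in self._cache:
            V = brownian_covariance(self.tree, list(species))
            self._cache[species] = scipy.linalg.cho_factor(V, lower=True)
        return self._cache[species]


def run_screen(
    matrix: pd.DataFrame,
    tree: dendropy.Tree,
    assignment: PhenotypeAssignment,
    *,
    fdr: float = 0.05,
    min_lineages: int = 3,
    loss_thr: float = 60.0,
    one_sided: bool = True,
    predictor: pd.Series | None = None,
) -> list[ScreenResult]:
    """Run the full forward-genomics screen.

    Steps: gene filtering, per-gene PGLS of %intact on the foreground
    indicator (or a supplied continuous predictor such as log10 acuity),
    BH correction over the retained gene universe, convergence counting
    over the foreground lineage partition, candidate flagging at
    ``q < fdr`` and ``n_lost_lineages >= min_lineages``.  Results are
    ranked by (q, p, gene_id).  Deterministic given inputs.
    """
    if not assignment.lineages:
        assignment = assignment.with_lineages(tree)
    mat = filter_genes(matrix, assignment)
    if mat.empty:
        return []
    fg = assignment.foreground
    labelled = assignment.foreground | assignment.background
    usable_cols = [c for c in mat.columns if c in labelled]
    mat = mat[usable_cols]
    if predictor is None:
        x_all = pd.Series(
            {sp: 1.0 if sp in fg else 0.0 for sp in usable_cols}
        )
    else:
        x_all = predictor
    cache = _CovarianceCache(tree)

    rows: list[dict] = []
    for gene_id, values in mat.iterrows():
        species = tuple(sorted(values.dropna().index))
        yv = values[list(species)].to_numpy(dtype=float)
        xv = x_all[list(species)].to_numpy(dtype=float)
        if len(species) < 3 or np.unique(xv).size < 2:
            log.debug("skipping %s: insufficient data", gene_id)
            continue
        degenerate = False
        if np.unique(yv).size < 2:
            slope, t, p = _DEGENERATE
            degenerate = True
        else:
            try:
                cho = cache.get(species)
            except np.linalg.LinAlgError:
                slope, t, p = _DEGENERATE
                degenerate = True
            else:
                slope, t, p = _gls(yv, xv, cho, one_sided=one_sided)
                degenerate = (slope, t, p) == _DEGENERATE
        statuses = loss_statuses(values, loss_thr)
        rows.append(
            dict(
                gene_id=gene_id,
                n_species_used=len(species),
                slope=slope,
                t_stat=t,
                p_value=p,
                n_lost_lineages=convergent_loss_count(
                    statuses, assignment.lineages
                ),
                degenerate=degenerate,
            )
        )
    if not rows:
        return []
    q = bh_adjust([r["p_value"] for r in rows])
    results = [
        ScreenResult(
            gene_id=r["gene_id"],
            n_species_used=r["n_species_used"],
            slope=r["slope"],
            t_stat=r["t_stat"],
            p_value=r["p_value"],
            q_value=float(qi),
            n_lost_lineages=r["n_lost_lineages"],
            candidate=bool(
                qi < fdr and r["n_lost_lineages"] >= min_lineages
            ),
            degenerate=r["degenerate"],
        )
        for r, qi in zip(rows, q)
    ]
    results.sort(key=lambda r: (r.q_value, r.p_value, r.gene_id))
    return results


def control_screen(
    matrix: pd.DataFrame,
    tree: dendropy.Tree,
    sister_foreground: set[str] | frozenset[str],
    **kwargs,
) -> list[ScreenResult]:
    """Re-run the screen with a substituted foreground set.

    Every species in the matrix that is not in ``sister_foreground`` is
    treated as background, mirroring the specificity control of searching
    for losses in the high-acuity sister species of the true foreground.
    """
    labels = {
        sp: (FOREGROUND if sp in sister_foreground else BACKGROUND)
        for sp in matrix.columns
    }
    assignment = PhenotypeAssignment(
        labels=labels, provenance={"method": "control"}
    ).with_lineages(tree)
    return run_screen(matrix, tree, assignment, **kwargs)


def results_frame(results: list[ScreenResult]) -> pd.DataFrame:
    """Screen results as a DataFrame with the canonical column order."""
    cols = [
        "gene_id",
        "n_species_used",
        "slope",
        "t_stat",
        "p_value",
        "q_value",
        "n_lost_lineages",
        "candidate",
    ]
    return pd.DataFrame(
        [{c: getattr(r, c) for c in cols} for r in results], columns=cols
    )
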