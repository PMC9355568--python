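"""PGLS association, BH correction, gene filtering, convergence counting.

The PGLS oracle is the explicit closed form (X'V^-1 X)^-1 X'V^-1 y with
matrices inverted by hand; the BH oracle is the direct step-up formula
m * p_(i) / i with a running minimum, implemented here independently of
the package.
"""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from fgscreen.phenotype import PhenotypeAssignment
from fgscreen.phylo import brownian_covariance
from fgscreen.screen import (
    bh_adjust,
    control_screen,
    convergent_loss_count,
    filter_genes,
    loss_statuses,
    pgls_fit,
    run_screen,
)

from conftest import make_tree


def bh_oracle(p):
    """Direct BH step-up: m*p_(i)/i with running minimum from the top."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = running
    return q


class TestPglsFit:
    def test_matches_closed_form_on_balanced_tree(self, balanced4):
        y = pd.Series({"A": 93.0, "B": 41.0, "C": 100.0, "D": 88.0})
        x = pd.Series({"A": 1.0, "B": 1.0, "C": 0.0, "D": 0.0})
        V = np.array(
            [
                [2.0, 1.0, 0.0, 0.0],
                [1.0, 2.0, 0.0, 0.0],
                [0.0, 0.0, 2.0, 1.0],
                [0.0, 0.0, 1.0, 2.0],
            ]
        )
        X = np.column_stack([np.ones(4), [1.0, 1.0, 0.0, 0.0]])
        yv = np.array([93.0, 41.0, 100.0, 88.0])
        Vi = np.linalg.inv(V)
        beta = np.linalg.inv(X.T @ Vi @ X) @ X.T @ Vi @ yv
        resid = yv - X @ beta
        s2 = resid @ Vi @ resid / 2
        se = np.sqrt(s2 * np.linalg.inv(X.T @ Vi @ X)[1, 1])
        t_exp = beta[1] / se
        p_exp = scipy.stats.t.cdf(t_exp, 2)

        slope, t, p = pgls_fit(y, x, balanced4)
        assert slope == pytest.approx(beta[1], abs=1e-10)
        assert t == pytest.approx(t_exp, abs=1e-10)
        assert p == pytest.approx(p_exp, abs=1e-10)

    def test_collapses_to_ols_on_star_tree(self, star6):
        rng = np.random.default_rng(4)
        sp = list("ABCDEF")
        y = pd.Series(rng.uniform(0, 100, 6), index=sp)
        x = pd.Series([1, 1, 1, 0, 0, 0], index=sp, dtype=float)
        X = np.column_stack([np.ones(6), x.to_numpy()])
        beta = np.linalg.inv(X.T @ X) @ X.T @ y.to_numpy()
        resid = y.to_numpy() - X @ beta
        s2 = resid @ resid / 4
        t_exp = beta[1] / np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])

        slope, t, p = pgls_fit(y, x, star6)
        assert slope == pytest.approx(beta[1], abs=1e-10)
        assert t == pytest.approx(t_exp, abs=1e-10)

    def test_constant_response_degenerates_to_p_one(self, balanced4):
        y = pd.Series({"A": 100.0, "B": 100.0, "C": 100.0, "D": 100.0})
        x = pd.Series({"A": 1.0, "B": 1.0, "C": 0.0, "D": 0.0})
        assert pgls_fit(y, x, balanced4) == (0.0, 0.0, 1.0)

    def test_missing_species_prunes_tree(self, balanced4):
        y = pd.Series({"A": 90.0, "B": 30.0, "C": 100.0, "D": np.nan})
        x = pd.Series({"A": 1.0, "B": 1.0, "C": 0.0, "D": 0.0})
        slope, t, p = pgls_fit(y, x, balanced4)
        assert np.isfinite(slope) and 0 <= p <= 1

    def test_single_class_rejected(self, balanced4):
        y = pd.Series({"A": 90.0, "B": 30.0, "C": 100.0, "D": 70.0})
        x = pd.Series({"A": 1.0, "B": 1.0, "C": 1.0, "D": 1.0})
        with pytest.raises(ValueError, match="class"):
            pgls_fit(y, x, balanced4)


class TestBrownianCovariance:
    def test_shared_path_lengths(self, balanced4):
        V = brownian_covariance(balanced4, ["A", "B", "C", "D"])
        expected = np.array(
            [
                [2.0, 1.0, 0.0, 0.0],
                [1.0, 2.0, 0.0, 0.0],
                [0.0, 0.0, 2.0, 1.0],
                [0.0, 0.0, 1.0, 2.0],
            ]
        )
        np.testing.assert_allclose(V, expected, atol=1e-12)


class TestBhAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_matches_direct_stepup_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            p = rng.uniform(size=rng.integers(1, 60))
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_sorted_qvalues_nondecreasing(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=100)
        q = bh_adjust(p)
        assert (np.diff(q[np.argsort(p)]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestFilterGenes:
    @pytest.fixture
    def assignment(self):
        labels = {f"f{i}": "foreground" for i in range(4)}
        labels.update({f"b{i}": "background" for i in range(4)})
        return PhenotypeAssignment(labels=labels)

    def test_drops_missing_heavy_and_constant(self, assignment):
        sp = [f"f{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        rows = {
            "ok": [50, 60, 70, 80, 90, 95, 100, 85],
            "fg_missing": [np.nan, np.nan, np.nan, 70, 90, 95, 100, 85],
            "constant": [100] * 8,
            "constant_with_na": [100, np.nan, 100, 100, 100, 100, 100, 100],
        }
        m = pd.DataFrame(rows, index=sp).T
        out = filter_genes(m, assignment)
        assert list(out.index) == ["ok"]

    def test_half_missing_is_kept(self, assignment):
        sp = [f"f{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        m = pd.DataFrame(
            {"edge": [np.nan, np.nan, 70, 80, 90, 95, 100, 85]}, index=sp
        ).T
        # exactly 50% foreground missing is not "more than 50%"
        assert list(filter_genes(m, assignment).index) == ["edge"]


class TestConvergence:
    def test_counts_lineages_not_species(self):
        lineages = [frozenset({"a", "b"}), frozenset({"c"}), frozenset({"d"})]
        statuses = {"a": "lost", "b": "lost", "c": "intact", "d": "missing"}
        assert convergent_loss_count(statuses, lineages) == 1

    def test_no_losses(self):
        lineages = [frozenset({"a"}), frozenset({"b"})]
        assert convergent_loss_count({"a": "intact"}, lineages) == 0

    def test_loss_statuses_thresholds(self):
        s = loss_statuses(pd.Series({"a": 59.9, "b": 60.0, "c": np.nan}))
        assert s == {"a": "lost", "b": "intact", "c": "missing"}


class TestRunScreen:
    @pytest.fixture
    def toy(self):
        tree = make_tree(
            "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);"
        )
        labels = {s: "foreground" for s in "ABC"}
        labels.update({s: "background" for s in "DEFGH"})
        assignment = PhenotypeAssignment(labels=labels)
        rng = np.random.default_rng(0)
        sp = list("ABCDEFGH")
        rows = {}
        for i in range(30):
            rows[f"null{i:02d}"] = np.clip(
                100 - rng.exponential(3, size=8), 0, 100
            )
        rows["hit"] = [10.0, 15.0, 20.0, 95.0, 100.0, 98.0, 97.0, 99.0]
        matrix = pd.DataFrame(rows, index=sp).T
        return matrix, tree, assignment

    def test_flags_strongly_associated_gene(self, toy):
        matrix, tree, assignment = toy
        res = run_screen(matrix, tree, assignment, min_lineages=2)
        by_gene = {r.gene_id: r for r in res}
        hit = by_gene["hit"]
        assert hit.slope < 0
        assert hit.n_lost_lineages == 2  # {A,B} clade and C
        assert res[0].gene_id == "hit"

    def test_permutation_invariance(self, toy):
        matrix, tree, assignment = toy
        a = run_screen(matrix, tree, assignment)
        shuffled = matrix.sample(frac=1, random_state=3)[
            list(matrix.columns)[::-1]
        ]
        b = run_screen(shuffled, tree, assignment)
        pa = {r.gene_id: (r.p_value, r.q_value) for r in a}
        pb = {r.gene_id: (r.p_value, r.q_value) for r in b}
        for g in pa:
            assert pa[g] == pytest.approx(pb[g], abs=1e-12)

    def test_candidate_set_monotone_in_fdr_and_lineages(self, toy):
        matrix, tree, assignment = toy

        def cands(fdr, ml):
            return {
                r.gene_id
                for r in run_screen(
                    matrix, tree, assignment, fdr=fdr, min_lineages=ml
                )
                if r.candidate
            }

        assert cands(0.01, 2) <= cands(0.05, 2) <= cands(0.2, 2)
        assert cands(0.2, 3) <= cands(0.2, 2) <= cands(0.2, 1)

    def test_control_screen_flips_slope_sign(self, toy):
        matrix, tree, assignment = toy
        main = {
            r.gene_id: r.slope for r in run_screen(matrix, tree, assignment)
        }
        ctrl = {
            r.gene_id: r.slope
            for r in control_screen(matrix, tree, frozenset("DEFGH"))
        }
        assert ctrl["hit"] == pytest.approx(-main["hit"], abs=1e-9)
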