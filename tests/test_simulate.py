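"""Synthetic-data generator: trees, phenotypes, gene histories, alignments.

The tree oracle is an independent forward implementation of the same
pure-birth process (divergence-time bookkeeping, no tree structure); the
mutation-count oracle is the Poisson path-length mean; the alignment
oracle is the implanted ground truth itself.
"""

import numpy as np
import pytest

from fgscreen.genescan import detect_mutations
from fgscreen.loss_mapping import shared_mutations
from fgscreen.phenotype import classify_by_acuity, partition_lineages
from fgscreen.simulate import (
    SimConfig,
    assign_phenotype,
    emit_alignments,
    matrix_from_mutations,
    simulate_dataset,
    simulate_gene,
    simulate_tree,
)


def yule_pairwise_mean(n, birth_rate, height, rng):
    """Mean pairwise leaf distance of one pure-birth tree, simulated
    independently of any tree library: track pairwise divergence times.
    Mirrors the generator's construction (stop at n-th birth, then one
    extra exponential hang time, then scale to fixed height)."""
    t = 0.0
    t_crown = None  # time of the first split (tree height is crown-to-tip)
    div = {}  # (i, j) -> divergence time
    lineages = [0]
    nxt = 1
    while len(lineages) < n:
        k = len(lineages)
        t += rng.exponential(1.0 / (birth_rate * k))
        if t_crown is None:
            t_crown = t
        parent = lineages[rng.integers(k)]
        child = nxt
        nxt += 1
        for other in lineages:
            if other != parent:
                key = tuple(sorted((other, child)))
                div[key] = div[tuple(sorted((other, parent)))]
        div[tuple(sorted((parent, child)))] = t
        lineages.append(child)
    t += rng.exponential(1.0 / (birth_rate * n))
    dists = [2 * (t - d) for d in div.values()]
    return np.mean(dists) * (height / (t - t_crown))


class TestSimulateTree:
    def test_two_species_cherry(self):
        tree = simulate_tree(2, seed=5, height=10.0)
        leaves = tree.leaf_nodes()
        assert len(leaves) == 2
        lens = [lf.edge.length for lf in leaves]
        assert lens[0] == pytest.approx(lens[1])
        assert lens[0] == pytest.approx(10.0)

    @pytest.mark.parametrize("n", [2, 5, 17, 49])
    def test_leaf_count_and_ultrametric(self, n):
        tree = simulate_tree(n, seed=n, height=100.0)
        depths = [lf.distance_from_root() for lf in tree.leaf_node_iter()]
        assert len(depths) == n
        assert max(depths) == pytest.approx(100.0)
        assert min(depths) == pytest.approx(100.0)
        assert min(
            nd.edge.length
            for nd in tree.preorder_node_iter()
            if nd.parent_node is not None
        ) > 0

    def test_reproducible_per_seed(self):
        a = simulate_tree(12, seed=9).as_string(schema="newick")
        b = simulate_tree(12, seed=9).as_string(schema="newick")
        c = simulate_tree(12, seed=10).as_string(schema="newick")
        assert a == b
        assert a != c

    def test_mean_pairwise_distance_matches_independent_simulation(self):
        n, height = 6, 50.0
        rng = np.random.default_rng(99)
        oracle = np.array(
            [yule_pairwise_mean(n, 1.0, height, rng) for _ in range(200)]
        )
        got = []
        for seed in range(200):
            tree = simulate_tree(n, seed=seed, height=height)
            pdm = tree.phylogenetic_distance_matrix()
            taxa = list(tree.taxon_namespace)
            d = [
                pdm.patristic_distance(a, b)
                for i, a in enumerate(taxa)
                for b in taxa[i + 1 :]
            ]
            got.append(np.mean(d))
        se = np.sqrt(
            (oracle.var() + np.var(got)) / 200
        )
        assert abs(np.mean(got) - oracle.mean()) < 3 * se


class TestAssignPhenotype:
    def test_round_trip_through_acuity_classifier(self):
        for seed in range(5):
            tree = simulate_tree(30, seed=seed)
            assignment, acuity = assign_phenotype(
                tree, 4, seed=seed, lineage_sizes=(2, 1, 1, 1), min_age_frac=0.0
            )
            recovered = classify_by_acuity(acuity, 1.0)
            assert recovered.foreground == assignment.foreground
            assert (
                partition_lineages(tree, assignment.foreground)
                == assignment.lineages
            )
            assert len(assignment.lineages) == 4

    def test_infeasible_request_rejected(self):
        tree = simulate_tree(4, seed=0)
        with pytest.raises(ValueError):
            assign_phenotype(tree, 4, seed=0, lineage_sizes=(2, 2, 2, 2))


class TestSimulateGene:
    @pytest.fixture
    def setup(self):
        cfg = SimConfig(
            n_species=8,
            n_fg_lineages=2,
            lineage_sizes=(2, 1),
            n_genes=1,
            n_associated=1,
            seed=3,
        )
        tree = simulate_tree(cfg.n_species, seed=cfg.seed, height=cfg.tree_height)
        assignment, _ = assign_phenotype(
            tree,
            cfg.n_fg_lineages,
            seed=cfg.seed,
            lineage_sizes=cfg.lineage_sizes,
            min_age_frac=0.0,
        )
        return cfg, tree, assignment

    def test_zero_rates_give_no_mutations(self, setup):
        cfg, tree, assignment = setup
        cfg0 = SimConfig(
            n_species=8,
            n_fg_lineages=2,
            lineage_sizes=(2, 1),
            n_genes=1,
            n_associated=1,
            lambda_fg=0.0,
            lambda_bg=0.0,
            seed=3,
        )
        muts = simulate_gene(tree, assignment, True, cfg0, seed=0)
        assert all(len(v) == 0 for v in muts.values())

    def test_poisson_mean_matches_path_length_oracle(self, setup):
        cfg, tree, assignment = setup
        height = cfg.tree_height
        fg_sp = sorted(assignment.lineages[0])[0]
        # foreground path length = height of the lineage stem's origin
        node = tree.find_node_with_taxon_label(fg_sp)
        while set(
            lf.taxon.label for lf in node.leaf_iter()
        ) != set(assignment.lineages[0]):
            node = node.parent_node
        fg_path = height - node.parent_node.distance_from_root()
        expected = cfg.lambda_fg * fg_path + cfg.lambda_bg * height
        counts = [
            len(
                simulate_gene(tree, assignment, True, cfg, seed=rep)[fg_sp]
            )
            for rep in range(1000)
        ]
        se = np.sqrt(expected / 1000)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_background_gene_ignores_foreground_rate(self, setup):
        cfg, tree, assignment = setup
        total = sum(
            len(v)
            for rep in range(200)
            for v in simulate_gene(
                tree, assignment, False, cfg, seed=rep
            ).values()
        )
        # only lambda_bg acts: expected count is tiny
        expect = cfg.lambda_bg * cfg.tree_height * 8 * 200
        assert total < expect + 3 * np.sqrt(expect) + 1

    def test_stem_mutations_are_shared_ancestrally(self, setup):
        cfg, tree, assignment = setup
        clade = sorted(next(l for l in assignment.lineages if len(l) > 1))
        hot = SimConfig(
            n_species=8,
            n_fg_lineages=2,
            lineage_sizes=(2, 1),
            n_genes=1,
            n_associated=1,
            lambda_fg=0.2,
            seed=3,
        )
        for rep in range(30):
            muts = simulate_gene(tree, assignment, True, hot, seed=rep)
            keys = [
                set(m.key for m in muts[sp]) for sp in clade
            ]
            shared_keys = set.intersection(*keys)
            if shared_keys:
                assignments, _ = shared_mutations(muts, tree)
                anc = {
                    a.codon_start
                    for a in assignments
                    if a.ancestral and a.species >= set(clade)
                }
                assert {k[1] for k in shared_keys} <= anc
                return
        pytest.fail("no replicate produced a shared stem mutation")


class TestEmitAlignments:
    def test_empty_mutation_list_gives_identity(self):
        alns = emit_alignments({"sp": []}, cds_len=120, seed=1)
        aln = alns["sp"]
        assert aln.ref_aln == aln.query_aln
        assert detect_mutations(aln) == []

    def test_round_trip_on_seeded_fixtures(self):
        """Implanted mutation sets are recovered exactly in kind and
        position across 120 simulated gene/species fixtures."""
        mismatches = 0
        checked = 0
        for seed in range(15):
            cfg = SimConfig(
                n_species=8,
                n_fg_lineages=2,
                lineage_sizes=(2, 1),
                n_genes=1,
                n_associated=1,
                lambda_fg=0.1,
                lambda_bg=0.005,
                seed=seed,
            )
            tree = simulate_tree(8, seed=seed, height=cfg.tree_height)
            assignment, _ = assign_phenotype(
                tree, 2, seed=seed, lineage_sizes=(2, 1), min_age_frac=0.0
            )
            muts = simulate_gene(tree, assignment, True, cfg, seed=seed)
            alns = emit_alignments(
                muts, cfg.cds_len, seed=seed, n_exons=cfg.n_exons
            )
            for sp, aln in alns.items():
                want = sorted((m.kind, m.codon_start) for m in muts[sp])
                got = sorted(
                    (m.kind, m.codon_start) for m in detect_mutations(aln)
                )
                checked += 1
                if want != got:
                    mismatches += 1
        assert checked >= 100
        assert mismatches == 0

    def test_matrix_reflects_lesions(self):
        cfg = SimConfig(
            n_species=6,
            n_fg_lineages=1,
            lineage_sizes=(2,),
            n_genes=3,
            n_associated=3,
            lambda_fg=0.3,
            seed=2,
        )
        truth = simulate_dataset(cfg)
        m = matrix_from_mutations(truth)
        assert m.shape == (3, 6)
        assert ((m >= 0) & (m <= 100)).all().all()
        clean = {
            sp
            for g in truth.mutations.values()
            for sp, evs in g.items()
            if not evs
        }
        for g, per_sp in truth.mutations.items():
            for sp, evs in per_sp.items():
                if not evs:
                    assert m.loc[g, sp] == 100.0
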