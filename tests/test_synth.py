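"""Generator: trees, sequence evolution, copy planting, HT scenarios."""

import numpy as np
import pytest

from tetrack import distmod, synth

REVC = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(REVC)[::-1]


class TestYuleTree:
    def test_two_leaves_is_cherry(self):
        t = synth.simulate_yule_tree(2, 1.0, seed=0)
        assert len(t.leaf_labels) == 2
        assert t.n_internal() == 1
        assert set(t.children[t.root]) == set(t.leaves)

    def test_same_seed_same_newick(self):
        a = synth.simulate_yule_tree(9, 2.0, seed=42).newick()
        b = synth.simulate_yule_tree(9, 2.0, seed=42).newick()
        assert a == b

    @pytest.mark.parametrize("n", [2, 5, 8, 16])
    def test_binary_tree_identity(self, n):
        t = synth.simulate_yule_tree(n, 1.0, seed=n)
        assert t.n_internal() == n - 1
        assert len(t.leaf_labels) == n

    def test_rejects_single_leaf(self):
        with pytest.raises(ValueError):
            synth.simulate_yule_tree(1, 1.0, seed=0)

    def test_height_rescaling_and_ultrametric(self):
        t = synth.simulate_yule_tree(6, 1.0, seed=3, height=0.4)
        assert t.height == pytest.approx(0.4)
        labs, d = t.patristic_matrix()
        # ultrametric: every leaf pair's distance <= 2*height
        assert d.max() <= 0.8 + 1e-12


class TestEvolve:
    def test_zero_branch_lengths_keep_root(self):
        t = synth.simulate_yule_tree(4, 1.0, seed=1, height=1.0)
        model = synth.SubstitutionModel(rate=1.0)
        zero = t.scaled(0.0)
        seqs = synth.evolve_along_tree("ACGT" * 25, zero, model, seed=9)
        assert all(s == "ACGT" * 25 for s in seqs.values())

    def test_rejects_non_acgt(self):
        t = synth.simulate_yule_tree(2, 1.0, seed=1)
        with pytest.raises(ValueError):
            synth.evolve_along_tree("ACGN", t, synth.SubstitutionModel(), 0)

    def test_high_kappa_suppresses_transversions(self, rng):
        root = synth.random_sequence(30000, rng)
        model = synth.SubstitutionModel(kind="K2P", kappa=5000.0)
        leaf = synth.evolve_sequence(root, 0.1, model, rng)
        counts = distmod.pair_site_counts(root, leaf)
        ts = counts["ts_pyrimidine"] + counts["ts_purine"]
        assert ts > 1000  # transitions did happen
        assert counts["tv"] <= 0.005 * ts

    @pytest.mark.parametrize("d", [0.01, 0.1, 0.5])
    def test_k2p_estimator_calibrated(self, d):
        """Mean K2P estimate over 50 replicate pairs is within 3 standard
        errors of the simulated divergence."""
        model = synth.SubstitutionModel(kind="K2P", kappa=2.0)
        ests = []
        for s in range(50):
            r = np.random.default_rng(900 + s)
            root = synth.random_sequence(8000, r)
            leaf = synth.evolve_sequence(root, d, model, r)
            ests.append(distmod.k2p_distance(root, leaf).distance)
        ests = np.asarray(ests)
        se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - d) <= 3 * se


class TestPlantCopies:
    def test_zero_age_zero_truncation_plants_identical(self, element):
        genome = synth.random_sequence(80000, np.random.default_rng(0))
        g2, truth = synth.plant_te_copies(
            genome, element, 5, ages=0.0, class_plan=["intact"] * 5, seed=1
        )
        assert len(truth.insertions) == 5
        for ins in truth.insertions:
            s = g2[ins.start : ins.end]
            if ins.strand == "-":
                s = revcomp(s)
            assert s == element.sequence
            assert ins.te_class == "intact"
            # TA duplication flanks every insertion
            assert g2[ins.start - 2 : ins.start] == "TA"
            assert g2[ins.end : ins.end + 2] == "TA"

    def test_zero_copies_unchanged(self, element):
        genome = synth.random_sequence(10000, np.random.default_rng(0))
        g2, truth = synth.plant_te_copies(genome, element, 0, seed=1)
        assert g2 == genome and truth.insertions == []

    def test_genome_shorter_than_element_rejected(self, element):
        with pytest.raises(ValueError):
            synth.plant_te_copies("TATATA", element, 1, seed=0)

    def test_truth_count_matches_exact_search(self, element):
        """Conservation: at age 0 every planted copy is findable by exact
        string search, and the counts agree with the truth table."""
        genome = synth.random_sequence(100000, np.random.default_rng(7))
        g2, truth = synth.plant_te_copies(
            genome, element, 6, ages=0.0, class_plan=["intact"] * 6, seed=3
        )
        fwd = g2.count(element.sequence)
        rev = g2.count(revcomp(element.sequence))
        assert fwd + rev == len(truth.insertions)

    def test_truncated_copies_lose_an_end(self, element):
        genome = synth.random_sequence(120000, np.random.default_rng(1))
        g2, truth = synth.plant_te_copies(
            genome, element, 8, ages=0.0, class_plan=["truncated"] * 8, seed=5
        )
        for ins in truth.insertions:
            s = g2[ins.start : ins.end]
            if ins.strand == "-":
                s = revcomp(s)
            assert len(s) <= 0.9 * element.length
            starts = s.startswith(element.tir_left)
            ends = s.endswith(element.tir_right)
            assert not (starts and ends)


class TestHTScenario:
    def test_transfer_at_time_zero_copies_donor(self, element):
        tree = synth.simulate_yule_tree(6, 1.0, seed=2, height=0.3)
        donor, recipient = tree.most_divergent_pair()
        spec = synth.TEHistorySpec(
            element=element, ht_directives=[(donor, recipient, 0.0)]
        )
        seqs, truth, _ = synth.apply_ht_scenario(tree, spec, seed=4)
        assert seqs[donor] == seqs[recipient]
        assert truth.ht_events == [(donor, recipient, 0.0)]

    def test_transfer_older_than_divergence_rejected(self, element):
        tree = synth.simulate_yule_tree(6, 1.0, seed=2, height=0.3)
        donor, recipient = tree.most_divergent_pair()
        too_old = tree.height * 1.5
        spec = synth.TEHistorySpec(
            element=element, ht_directives=[(donor, recipient, too_old)]
        )
        with pytest.raises(synth.InvalidScenarioError):
            synth.apply_ht_scenario(tree, spec, seed=4)

    def test_vertical_te_distances_track_host_distances(self, element):
        """Equal-rate vertical descent: element and host distance matrices
        are strongly correlated (gene-tree noise only)."""
        tree = synth.simulate_yule_tree(8, 1.0, seed=11, height=0.3)
        model = synth.SubstitutionModel()
        rng = np.random.default_rng(0)
        host_root = synth.random_sequence(50000, rng)
        host = synth.evolve_along_tree(host_root, tree, model, seed=21)
        te_root = synth.random_sequence(50000, rng)
        te = synth.evolve_along_tree(te_root, tree, model, seed=22)
        labs = tree.leaf_labels
        dh, dt = [], []
        for i in range(len(labs)):
            for j in range(i + 1, len(labs)):
                dh.append(distmod.k2p_distance(host[labs[i]], host[labs[j]]).distance)
                dt.append(distmod.k2p_distance(te[labs[i]], te[labs[j]]).distance)
        r = np.corrcoef(dh, dt)[0, 1]
        assert r > 0.99

    def test_recent_transfer_inverts_distance_ranking(self, element):
        """After a recent transfer between the two most distant leaves, that
        pair has the smallest element distance but the largest host
        distance."""
        study = synth.simulate_ht_study(
            10, seed=77, tree_height=0.5, ht="most_divergent", ht_time=0.005
        )
        donor, recipient, _ = study.truth.ht_events[0]
        labs = study.tree.leaf_labels
        te_d = {}
        host_d = {}
        for i in range(len(labs)):
            for j in range(i + 1, len(labs)):
                a, b = labs[i], labs[j]
                te_d[(a, b)] = distmod.k2p_distance(
                    study.te_seqs[a], study.te_seqs[b]
                ).distance
                host_d[(a, b)] = distmod.k2p_distance(
                    study.gene_seqs["RPL3"][a], study.gene_seqs["RPL3"][b]
                ).distance
        pair = (donor, recipient) if (donor, recipient) in te_d else (recipient, donor)
        assert te_d[pair] == min(te_d.values())
        # the planted pair is the deepest split; its host-gene estimate sits
        # at the top of the matrix up to estimation noise
        assert host_d[pair] >= 0.95 * max(host_d.values())
        assert study.tree.patristic(donor, recipient) == pytest.approx(
            max(
                study.tree.patristic(a, b)
                for i, a in enumerate(labs)
                for b in labs[i + 1 :]
            )
        )

    def test_outputs_deterministic_in_seed(self, element):
        a = synth.simulate_ht_study(6, seed=5, ht="most_divergent")
        b = synth.simulate_ht_study(6, seed=5, ht="most_divergent")
        assert a.te_seqs == b.te_seqs
        assert a.gene_seqs == b.gene_seqs
        assert a.truth.ht_events == b.truth.ht_events


class TestElementConstruction:
    def test_element_structure(self, element):
        assert element.tir_right == revcomp(element.tir_left)
        assert element.protein_aa == 492
        assert element.sequence[element.orf_start : element.orf_start + 3] == "ATG"
        assert element.sequence[element.orf_end - 3 : element.orf_end] in (
            "TAA",
            "TAG",
            "TGA",
        )

    def test_disrupted_orf_below_intact_threshold(self, element):
        from tetrack import annotate

        dead = synth.disrupt_orf(element, np.random.default_rng(0))
        orf = annotate.find_longest_orf(dead)
        assert orf is None or orf.protein_aa <= 300
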