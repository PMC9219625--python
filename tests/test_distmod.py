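"""Distances, alignment, and neighbor joining against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import (
    affine_dp_score,
    k2p_closed_form,
    tn93_closed_form,
    unrooted_splits,
)
from tetrack import distmod, synth


def random_pair(seed: int, n: int, d: float):
    rng = np.random.default_rng(seed)
    a = synth.random_sequence(n, rng)
    b = synth.evolve_sequence(a, d, synth.SubstitutionModel(), rng)
    return a, b


class TestAlignPair:
    def test_identical_sequences(self):
        aln = distmod.align_pair("ACGTACGT", "ACGTACGT")
        assert distmod.percent_identity(aln) == 1.0
        assert aln.gap_columns == 0

    def test_insertion_makes_one_gap_run(self):
        a = "ACGTACGTACGTACGTACGT"
        b = a[:10] + "TTTTT" + a[10:]
        aln = distmod.align_pair(a, b)
        gaps = "".join("-" if c == "-" else "x" for c in aln.seq_a)
        assert gaps.count("-") == 5
        assert "-----" in gaps  # a single run

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            distmod.align_pair("", "ACGT")

    @pytest.mark.parametrize("seed", range(10))
    def test_score_matches_exhaustive_dp(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            a = synth.random_sequence(10, rng)
            b = synth.random_sequence(10, rng)
            aln = distmod.align_pair(a, b)
            assert aln.score == pytest.approx(affine_dp_score(a, b))

    def test_roundtrip_recovers_inputs(self):
        a, b = random_pair(3, 200, 0.2)
        aln = distmod.align_pair(a, b)
        assert aln.seq_a.replace("-", "") == a
        assert aln.seq_b.replace("-", "") == b


class TestPercentIdentity:
    def test_fraction_of_gapfree_columns(self):
        aln = distmod.PairAlignment("ACGT-A", "ACTTTA", score=0)
        # columns: A/A C/C G/T T/T -/T A/A -> 4 matches / 5 gap-free
        assert distmod.percent_identity(aln) == pytest.approx(4 / 5)

    def test_all_gap_columns_error(self):
        aln = distmod.PairAlignment("--", "AA", score=0)
        with pytest.raises(ValueError):
            distmod.percent_identity(aln)


class TestK2P:
    def test_identical_zero(self):
        assert distmod.k2p_distance("ACGTACGT", "ACGTACGT").distance == 0.0

    def test_frozen_closed_form_values(self):
        # d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)
        assert distmod.k2p_from_counts(0.01, 0.0).distance == pytest.approx(
            0.010101353658759733, abs=1e-12
        )
        assert distmod.k2p_from_counts(0.01, 0.02).distance == pytest.approx(
            0.030616495890191373, abs=1e-12
        )

    def test_saturation_flag(self):
        est = distmod.k2p_from_counts(0.5, 0.1)
        assert est.saturated and math.isinf(est.distance)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_k2p_at_least_p_distance(self, seed):
        a, b = random_pair(seed, 500, 0.15)
        k2p = distmod.k2p_distance(a, b)
        if not k2p.saturated:
            assert k2p.distance >= distmod.p_distance(a, b).distance - 1e-12

    def test_matches_independent_closed_form(self):
        for seed in range(50):
            a, b = random_pair(seed, 1000, 0.1)
            c = distmod.pair_site_counts(a, b)
            p = (c["ts_pyrimidine"] + c["ts_purine"]) / c["sites"]
            q = c["tv"] / c["sites"]
            assert distmod.k2p_distance(a, b).distance == pytest.approx(
                k2p_closed_form(p, q), abs=1e-12
            )


class TestMCLMatrix:
    def test_identical_sequences_zero_matrix(self):
        dm = distmod.mcl_distance_matrix(["ACGT" * 50] * 4)
        assert np.all(dm.values == 0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_two_sequence_case_equals_tn93_closed_form(self, seed):
        model = synth.SubstitutionModel(
            kind="TN93", kappa=4.0, kappa2=2.0, freqs=(0.3, 0.2, 0.25, 0.25)
        )
        rng = np.random.default_rng(seed)
        a = synth.random_sequence(5000, rng, freqs=(0.3, 0.2, 0.25, 0.25))
        b = synth.evolve_sequence(a, 0.12, model, rng)
        dm = distmod.mcl_distance_matrix({"a": a, "b": b})
        assert dm.values[0, 1] == pytest.approx(tn93_closed_form(a, b), abs=1e-9)

    def test_symmetric_zero_diagonal(self):
        seqs = [random_pair(s, 400, 0.2)[1] for s in range(5)]
        dm = distmod.mcl_distance_matrix(seqs)
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0.0)

    def test_calibrated_on_tn93_simulation(self):
        """Estimates at d=0.1 over 10 kb are within 3 standard errors."""
        model = synth.SubstitutionModel(
            kind="TN93", kappa=3.0, kappa2=2.0, freqs=(0.3, 0.2, 0.2, 0.3)
        )
        ests = []
        for s in range(30):
            rng = np.random.default_rng(500 + s)
            a = synth.random_sequence(10000, rng, freqs=(0.3, 0.2, 0.2, 0.3))
            b = synth.evolve_sequence(a, 0.1, model, rng)
            ests.append(distmod.mcl_distance_matrix({"a": a, "b": b}).values[0, 1])
        ests = np.asarray(ests)
        se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - 0.1) <= 3 * se

    def test_saturated_pair_flagged_not_dropped(self):
        rng = np.random.default_rng(0)
        a = synth.random_sequence(300, rng)
        b = synth.random_sequence(300, rng)  # unrelated ~ saturated
        c = synth.evolve_sequence(a, 0.05, synth.SubstitutionModel(), rng)
        dm = distmod.mcl_distance_matrix({"a": a, "b": b, "c": c})
        assert dm.values.shape == (3, 3)
        # the related pair stays finite and sane
        assert dm.get("a", "c") < 0.2


class TestIdentityMatrix:
    def test_matches_hand_count(self):
        dm = distmod.identity_matrix({"x": "AAAA", "y": "AAAT", "z": "TTTT"})
        assert dm.get("x", "y") == pytest.approx(0.75)
        assert dm.get("x", "z") == 0.0
        assert dm.get("x", "x") == 1.0


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        # d(ab)=0.3, d(ac)=0.5, d(bc)=0.6 -> la=(0.3+0.5-0.6)/2=0.1,
        # lb=0.2, lc=0.4; check patristic sums on the output tree
        import dendropy

        dm = distmod.DistanceMatrix(
            ["a", "b", "c"],
            np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]]),
        )
        t = dendropy.Tree.get(data=distmod.nj_tree(dm), schema="newick")
        pdm = t.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in t.taxon_namespace}
        assert pdm.distance(taxa["a"], taxa["b"]) == pytest.approx(0.3)
        assert pdm.distance(taxa["a"], taxa["c"]) == pytest.approx(0.5)
        assert pdm.distance(taxa["b"], taxa["c"]) == pytest.approx(0.6)

    @pytest.mark.parametrize("seed", range(20))
    def test_recovers_topology_from_additive_matrix(self, seed):
        n = 4 + seed % 7  # 4..10 taxa
        tree = synth.simulate_yule_tree(n, 1.0, seed=seed)
        labs, d = tree.patristic_matrix()
        nwk = distmod.nj_tree(distmod.DistanceMatrix(labs, d))
        assert unrooted_splits(nwk, labs) == unrooted_splits(tree.newick(), labs)

    def test_equal_distances_deterministic(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = distmod.DistanceMatrix(list("abcd"), d)
        assert distmod.nj_tree(dm) == distmod.nj_tree(dm)

    def test_rejects_asymmetric_matrix(self):
        d = np.array([[0, 1.0, 1], [2, 0, 1], [1, 1, 0]])
        with pytest.raises(ValueError):
            distmod.DistanceMatrix(list("abc"), d)

    def test_agrees_with_skbio_on_noisy_matrices(self):
        """Independent cross-check: scikit-bio's NJ and ours give the same
        topology on perturbed additive matrices."""
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        for seed in range(5):
            tree = synth.simulate_yule_tree(7, 1.0, seed=100 + seed)
            labs, d = tree.patristic_matrix()
            rng = np.random.default_rng(seed)
            noise = rng.normal(0, 0.01, size=d.shape)
            noise = (noise + noise.T) / 2
            np.fill_diagonal(noise, 0)
            d = np.abs(d + noise)
            d = (d + d.T) / 2
            mine = distmod.nj_tree(distmod.DistanceMatrix(labs, d))
            theirs = str(sk_nj(SkDM(d, ids=labs)))
            assert unrooted_splits(mine, labs) == unrooted_splits(theirs, labs)
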