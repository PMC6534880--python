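import numpy as np
import pytest

from smilesrl.evaluate import (
    PHYSCHEM_NAMES,
    batch_report,
    cluster_compare,
    has_fused_ring,
    internal_diversity,
    murcko_scaffold,
    physchem,
    project_space,
    rank_candidates,
    substructure_flags,
    substructure_stats,
    tanimoto_distance,
    tanimoto_similarity,
)
from smilesrl.qsar import PredictorModel, compute_ecfp6


class TestTanimoto:
    def test_identical_nonempty(self):
        fp = frozenset({1, 5, 9})
        assert tanimoto_similarity(fp, fp) == 1.0

    def test_disjoint(self):
        assert tanimoto_similarity(frozenset({1, 2}), frozenset({3, 4})) == 0.0

    def test_arithmetic(self):
        ma = frozenset({1, 2, 3})
        mb = frozenset({2, 3, 4})
        assert tanimoto_similarity(ma, mb) == pytest.approx(0.5)  # |∩|=2, |∪|=4

    def test_both_empty_convention(self):
        assert tanimoto_similarity(frozenset(), frozenset()) == 0.0
        assert tanimoto_distance(frozenset(), frozenset()) == 1.0

    def test_symmetric(self):
        ma = compute_ecfp6("CCO")
        mb = compute_ecfp6("c1ccoc1")
        assert tanimoto_similarity(ma, mb) == tanimoto_similarity(mb, ma)


def brute_force_diversity(fps):
    n = len(fps)
    total = 0.0
    for a in fps:
        for b in fps:
            total += tanimoto_distance(a, b)
    return total / (n * n)


class TestInternalDiversity:
    def test_identical_set_is_zero(self):
        assert internal_diversity(["CCO"] * 5) == 0.0

    def test_two_maximally_distant(self):
        # two disjoint fingerprints: T_d matrix [[0,1],[1,0]] -> mean 0.5
        fps = [frozenset({1, 2}), frozenset({3, 4})]
        assert internal_diversity([], fps=fps) == pytest.approx(0.5)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            n = int(rng.integers(5, 31))
            fps = [frozenset(rng.integers(0, 4096, size=25).tolist())
                   for _ in range(n)]
            assert internal_diversity([], fps=fps) == pytest.approx(
                brute_force_diversity(fps), abs=1e-12)

    def test_self_pair_dilution_bound(self):
        smiles = ["CCO", "c1ccoc1", "c1ccccc1", "CCN", "C1CCCCC1"]
        n = len(smiles)
        div = internal_diversity(smiles)
        assert 0.0 <= div <= (n - 1) / n

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            internal_diversity([])


class TestBatchReport:
    def test_repeated_single_molecule(self, constant_estimator_cls):
        predictor = PredictorModel("RF", constant_estimator_cls(0.9))
        rep = batch_report(["CCO"] * 10, predictor)
        assert rep.valid_pct == 100.0
        assert rep.desired_pct == 100.0
        assert rep.unique_pct == 10.0
        assert rep.diversity == 0.0

    def test_all_invalid(self, constant_estimator_cls):
        predictor = PredictorModel("RF", constant_estimator_cls(0.9))
        rep = batch_report(["xx", "yy", "zz", "ww"], predictor)
        assert rep.valid_pct == 0.0
        assert rep.desired_pct == 0.0
        assert rep.unique_pct == 100.0

    def test_crafted_batch_matches_hand_enumeration(self, stub_estimator_cls):
        # one-bit predictor: desired iff the molecule contains a bit unique
        # to furan-containing structures
        furan_bits = compute_ecfp6("c1ccoc1") & compute_ecfp6("Cc1ccoc1")
        other_bits = compute_ecfp6("CCO") | compute_ecfp6("CCC")
        bit = sorted(furan_bits - other_bits)[0]
        predictor = PredictorModel("RF", stub_estimator_cls(bit))
        batch = ["Cc1ccoc1", "Cc1ccoc1", "CCO", "CCC", "xyz", "c1ccoc1"]
        # hand enumeration: 5/6 valid; desired = {2x Cc1ccoc1, c1ccoc1} = 3/6;
        # unique keys = {Cc1ccoc1, CCO, CCC, xyz, c1ccoc1} = 5/6;
        # unique desired = {Cc1ccoc1, c1ccoc1} = 2/6
        rep = batch_report(batch, predictor)
        assert rep.n == 6
        assert rep.valid_pct == pytest.approx(100 * 5 / 6)
        assert rep.desired_pct == pytest.approx(100 * 3 / 6)
        assert rep.unique_pct == pytest.approx(100 * 5 / 6)
        assert rep.unique_desired_pct == pytest.approx(100 * 2 / 6)
        assert rep.unique_of_desired_pct == pytest.approx(100 * 2 / 3)
        expected_div = brute_force_diversity(
            [compute_ecfp6("Cc1ccoc1"), compute_ecfp6("c1ccoc1")])
        assert rep.diversity == pytest.approx(expected_div, abs=1e-12)

    def test_percentages_recomputed_by_independent_loop(self, rf_predictor):
        from smilesrl.fixtures import FixtureConfig, generate_corpus
        from smilesrl.vocab import canonical_smiles, is_valid_smiles
        batch = generate_corpus(FixtureConfig(n_molecules=60, seed=3))
        batch += ["xx", "C("]
        rep = batch_report(batch, rf_predictor)
        n = len(batch)
        n_valid = sum(1 for s in batch if is_valid_smiles(s))
        keys = {canonical_smiles(s) or f"~{s}" for s in batch}
        assert rep.valid_pct == pytest.approx(100 * n_valid / n)
        assert rep.unique_pct == pytest.approx(100 * len(keys) / n)
        n_desired = 0
        for s in batch:
            if is_valid_smiles(s) and rf_predictor.predict_q_smiles(s) > 0.5:
                n_desired += 1
        assert rep.desired_pct == pytest.approx(100 * n_desired / n)

    def test_empty_batch_raises(self, constant_estimator_cls):
        predictor = PredictorModel("RF", constant_estimator_cls(0.5))
        with pytest.raises(ValueError):
            batch_report([], predictor)


# hand-labeled 12-molecule fixture: (smiles, fused, furan, benzene)
SUBSTRUCTURE_FIXTURE = [
    ("c1ccccc1", False, False, True),
    ("c1ccoc1", False, True, False),
    ("c1ccc2ccccc2c1", True, False, True),        # naphthalene
    ("Cc1ccccc1", False, False, True),            # toluene
    ("C1CCCCC1", False, False, False),            # cyclohexane
    ("CCO", False, False, False),
    ("C1CC12CC2", False, False, False),           # spiropentane: not fused
    ("c1ccc2occc2c1", True, True, True),          # benzofuran
    ("C1CCC2CCCCC2C1", True, False, False),       # decalin
    ("Cc1ccoc1", False, True, False),
    ("c1ccc(-c2ccco2)cc1", False, True, True),    # 2-phenylfuran
    ("CC(=O)Nc1ccccc1", False, False, True),      # acetanilide
]


class TestSubstructures:
    @pytest.mark.parametrize("smiles,fused,furan,benzene", SUBSTRUCTURE_FIXTURE)
    def test_flags_match_hand_labels(self, smiles, fused, furan, benzene):
        flags = substructure_flags(smiles)
        assert flags["fused_ring"] is fused
        assert flags["furan_ring"] is furan
        assert flags["benzene_ring"] is benzene

    def test_stats_are_percentages_of_flags(self):
        smiles = [s for s, *_ in SUBSTRUCTURE_FIXTURE]
        stats = substructure_stats(smiles)
        n = len(smiles)
        assert stats["fused_ring"] == pytest.approx(
            100 * sum(f for _, f, _, _ in SUBSTRUCTURE_FIXTURE) / n)
        assert stats["furan_ring"] == pytest.approx(
            100 * sum(f for _, _, f, _ in SUBSTRUCTURE_FIXTURE) / n)
        assert stats["benzene_ring"] == pytest.approx(
            100 * sum(f for _, _, _, f in SUBSTRUCTURE_FIXTURE) / n)

    def test_spiro_not_fused(self):
        from rdkit import Chem
        assert not has_fused_ring(Chem.MolFromSmiles("C1CC12CC2"))


class TestPhysChem:
    def test_methane(self):
        d = physchem("C")
        assert d["heavy_atoms"] == 1
        assert d["rings"] == 0
        assert d["heteroatoms"] == 0

    def test_benzene(self):
        d = physchem("c1ccccc1")
        assert d["aromatic_rings"] == 1
        assert d["saturated_rings"] == 0
        assert d["fraction_csp3"] == 0.0

    def test_ethanol(self):
        d = physchem("CCO")
        assert d["hbd"] == 1
        assert d["heteroatoms"] == 1

    def test_has_19_descriptors(self):
        assert len(PHYSCHEM_NAMES) == 19
        assert set(physchem("CCO")) == set(PHYSCHEM_NAMES)

    def test_invalid_raises(self):
        with pytest.raises(ValueError):
            physchem("xyz")


class TestProjectSpace:
    def test_pca_preserves_2d_distances(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 2))
        Y = project_space(X, "PCA")
        from scipy.spatial.distance import pdist
        assert np.allclose(pdist(X), pdist(Y), atol=1e-9)

    def test_pca_variance_non_increasing(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 6)) * np.array([5, 3, 1, 1, 1, 1])
        Y = project_space(X, "PCA")
        assert Y[:, 0].var() >= Y[:, 1].var()

    def test_duplicate_points_identical(self):
        X = np.array([[1.0, 2.0, 3.0]] * 2 + [[0.0, 0.0, 1.0], [4.0, 1.0, 0.0]])
        Y = project_space(X, "PCA")
        assert np.allclose(Y[0], Y[1])

    def test_tsne_seeded_shape(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 5))
        Y1 = project_space(X, "tSNE", seed=3)
        Y2 = project_space(X, "tSNE", seed=3)
        assert Y1.shape == (30, 2)
        assert np.allclose(Y1, Y2)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            project_space(np.zeros((2, 4)))


class TestClusterCompare:
    REFERENCE = [s for s, *_ in SUBSTRUCTURE_FIXTURE]

    def test_self_comparison_coverage_one(self):
        occ = cluster_compare(self.REFERENCE, self.REFERENCE, k=4, seed=0)
        assert np.array_equal(occ.reference_counts, occ.query_counts)
        assert occ.coverage == 1.0

    def test_occupancy_sums(self):
        query = ["CCO", "CCN", "CCCC", "c1ccccc1O"]
        occ = cluster_compare(self.REFERENCE, query, k=3, seed=0)
        assert occ.reference_counts.sum() == len(self.REFERENCE)
        assert occ.query_counts.sum() == len(query)

    def test_murcko_scaffold_of_toluene_is_benzene(self):
        # scaffold-extraction oracle
        assert murcko_scaffold("Cc1ccccc1") == "c1ccccc1"

    def test_topological_scaffold_abstracts_atoms(self):
        # pyridine's generic scaffold is the plain carbon 6-ring
        assert murcko_scaffold("c1ccncc1", topological=True) == "C1CCCCC1"

    def test_k_too_large_raises(self):
        with pytest.raises(ValueError):
            cluster_compare(["CCO"], ["CCN"], k=5)

    def test_bad_mode_raises(self):
        with pytest.raises(ValueError):
            cluster_compare(self.REFERENCE, self.REFERENCE, k=2, mode="nope")


class TestRankCandidates:
    def test_reference_member_distance_zero(self, constant_estimator_cls):
        predictor = PredictorModel("RF", constant_estimator_cls(0.5))
        rows = rank_candidates(["CCO"], predictor, reference=["CCO", "CCN"])
        assert rows[0][2] == 0.0

    def test_equal_q_tie_break_by_distance(self, constant_estimator_cls):
        predictor = PredictorModel("RF", constant_estimator_cls(0.5))
        rows = rank_candidates(["CCO", "c1ccoc1"], predictor,
                               reference=["CCO"])
        assert rows[0][0] == "c1ccoc1"  # more distant ranks first on tie

    def test_top_n_larger_than_set(self, constant_estimator_cls):
        predictor = PredictorModel("RF", constant_estimator_cls(0.5))
        rows = rank_candidates(["CCO", "CCN"], predictor, reference=["CCO"],
                               top_n=10)
        assert len(rows) == 2

    def test_sorted_by_q_descending(self, stub_estimator_cls):
        bit = sorted(compute_ecfp6("c1ccoc1") - compute_ecfp6("CCO"))[0]
        predictor = PredictorModel("RF", stub_estimator_cls(bit))
        rows = rank_candidates(["CCO", "c1ccoc1"], predictor,
                               reference=["CCN"])
        assert rows[0][0] == "c1ccoc1"
        assert rows[0][1] > rows[1][1]

    def test_empty_reference_raises(self, constant_estimator_cls):
        predictor = PredictorModel("RF", constant_estimator_cls(0.5))
        with pytest.raises(ValueError):
            rank_candidates(["CCO"], predictor, reference=[])
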