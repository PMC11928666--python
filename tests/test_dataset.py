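import numpy as np
import pytest

from _utils import mutate, random_seq
from ayu.dataset import (Cluster, candidate_pairs, cross_fold_violations,
                         global_identity, greedy_cluster, homology_partition,
                         identity_edges, propagate_annotation,
                         smote_oversample)
from ayu.seq_io import LocalizationLabel, ProteinRecord


def gotoh_global(a, b, open_cost=11.0, extend_cost=1.0):
    """Independent affine-gap global alignment (score + one traceback),
    written as a plain dynamic program.  The first gap residue costs
    ``open_cost``, each further residue ``extend_cost``; end gaps are
    penalized like internal ones."""
    from Bio.Align import substitution_matrices
    sub = substitution_matrices.load("BLOSUM62")
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)   # gap in b (a advances)
    Iy = np.full((n + 1, m + 1), NEG)   # gap in a (b advances)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -open_cost - (i - 1) * extend_cost
    for j in range(1, m + 1):
        Iy[0, j] = -open_cost - (j - 1) * extend_cost
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1],
                          Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(M[i - 1, j] - open_cost, Ix[i - 1, j] - extend_cost)
            Iy[i, j] = max(M[i, j - 1] - open_cost, Iy[i, j - 1] - extend_cost)
    score = max(M[n, m], Ix[n, m], Iy[n, m])
    # traceback for identity / alignment length
    i, j = n, m
    state = int(np.argmax([M[n, m], Ix[n, m], Iy[n, m]]))
    identities = cols = 0
    while i > 0 or j > 0:
        cols += 1
        if state == 0:
            identities += int(a[i - 1] == b[j - 1])
            s = sub[a[i - 1], b[j - 1]]
            prev = [M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]]
            state = int(np.argmax(prev))
            i, j = i - 1, j - 1
        elif state == 1:
            state = 0 if M[i - 1, j] - open_cost >= Ix[i - 1, j] - extend_cost \
                else 1
            i -= 1
        else:
            state = 0 if M[i, j - 1] - open_cost >= Iy[i, j - 1] - extend_cost \
                else 2
            j -= 1
    return score, identities / cols


class TestGlobalIdentity:
    def test_identical_sequences(self):
        e = global_identity("MKTAYIAKQR", "MKTAYIAKQR")
        assert e.identity == 1.0 and e.coverage == 1.0

    def test_disjoint_alphabets(self):
        assert global_identity("AAAA", "WWWW").identity == 0.0

    def test_symmetric(self, rng):
        a, b = random_seq(rng, 40), random_seq(rng, 35)
        e1, e2 = global_identity(a, b), global_identity(b, a)
        assert e1.identity == pytest.approx(e2.identity)
        assert e1.coverage == pytest.approx(e2.coverage)

    def test_matches_independent_dp_oracle(self):
        a, b = "HEAGAWGHEE", "PAWHEAE"
        oracle_score, oracle_identity = gotoh_global(a, b)
        from ayu.dataset import make_aligner
        aligner = make_aligner()
        assert aligner.score(a, b) == pytest.approx(oracle_score)
        e = global_identity(a, b)
        assert e.identity == pytest.approx(oracle_identity)

    def test_oracle_on_random_pairs(self, rng):
        from ayu.dataset import make_aligner
        aligner = make_aligner()
        for _ in range(5):
            a, b = random_seq(rng, 25), random_seq(rng, 20)
            score, _ = gotoh_global(a, b)
            assert aligner.score(a, b) == pytest.approx(score)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            global_identity("", "AAA")


class TestPropagation:
    def setup_method(self):
        rng = np.random.default_rng(3)
        self.ref = ProteinRecord("ref", random_seq(rng, 100))
        self.near = ProteinRecord("near", mutate(rng, self.ref.seq, 0.3))
        self.far = ProteinRecord("far", random_seq(rng, 100))
        self.label = LocalizationLabel.PERIPLASMIC

    def test_propagates_when_identity_and_domains_match(self):
        got = propagate_annotation(self.near, self.ref, self.label,
                                   ["PF1", "PF2"], ["PF1", "PF2"])
        assert got == self.label

    def test_below_identity_threshold_blocks(self):
        assert propagate_annotation(self.far, self.ref, self.label,
                                    ["PF1"], ["PF1"]) is None

    def test_domain_order_matters(self):
        # same domain content, different synteny: no transfer
        assert propagate_annotation(self.near, self.ref, self.label,
                                    ["PF2", "PF1"], ["PF1", "PF2"]) is None

    def test_domain_content_matters(self):
        assert propagate_annotation(self.near, self.ref, self.label,
                                    ["PF1"], ["PF1", "PF2"]) is None


class TestGreedyCluster:
    def test_identical_pair_one_cluster(self, rng):
        seq = random_seq(rng, 60)
        recs = [ProteinRecord("a", seq), ProteinRecord("b", seq)]
        clusters = greedy_cluster(recs, 0.9, 0.9)
        assert len(clusters) == 1 and len(clusters[0].members) == 2

    def test_strict_thresholds_all_singletons(self, rng):
        recs = [ProteinRecord(f"s{i}", random_seq(rng, 50)) for i in range(4)]
        clusters = greedy_cluster(recs, 1.0, 1.0)
        assert len(clusters) == 4

    def test_pairwise_matrix_oracle(self, rng):
        base = random_seq(rng, 80)
        recs = [ProteinRecord("A", base),
                ProteinRecord("B", mutate(rng, base, 0.1)),
                ProteinRecord("C", random_seq(rng, 80))]
        ab = global_identity(recs[0], recs[1]).identity
        ac = global_identity(recs[0], recs[2]).identity
        assert ab > 0.7 and ac < 0.7  # fixture precondition
        clusters = greedy_cluster(recs, 0.7, 0.8)
        assert sorted(sorted(c.members) for c in clusters) == \
            [["A", "B"], ["C"]]

    def test_representative_prefers_reference_match(self, rng):
        seq = random_seq(rng, 60)
        recs = [ProteinRecord("long", seq + "AAAA"), ProteinRecord("short", seq)]
        by_ref = greedy_cluster(recs, 0.8, 0.8,
                                ref_identity={"short": 0.9, "long": 0.2})
        assert by_ref[0].representative == "short"
        by_len = greedy_cluster(recs, 0.8, 0.8)
        assert by_len[0].representative == "long"

    def test_deterministic(self, rng):
        recs = [ProteinRecord(f"s{i}", random_seq(rng, 60)) for i in range(6)]
        c1 = greedy_cluster(recs, 0.5, 0.5)
        c2 = greedy_cluster(recs, 0.5, 0.5)
        assert [(c.representative, c.members) for c in c1] == \
            [(c.representative, c.members) for c in c2]

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            greedy_cluster([], 0.0, 0.5)


class TestHomologyPartition:
    def test_unrelated_records_stratified(self, rng):
        records, labels = [], {}
        classes = list(LocalizationLabel)
        for i in range(60):
            records.append(ProteinRecord(f"u{i}", random_seq(rng, 60)))
            labels[f"u{i}"] = classes[i % 3]
        assign = homology_partition(records, labels, (0.7, 0.15, 0.15),
                                    seed=0)
        for split, frac in zip(("train", "val", "test"), (0.7, 0.15, 0.15)):
            ids = assign.split(split)
            for cls in classes:
                n = sum(labels[i] == cls for i in ids)
                assert abs(n - frac * 20) <= 1

    def test_transitive_chain_stays_together(self, rng):
        # A-B and B-C share segments (identity above threshold); A-C share
        # nothing.  The component {A, B, C} must land in a single fold.
        s1, s2, s3, s4 = (random_seq(rng, 60) for _ in range(4))
        recs = [ProteinRecord("A", s1 + s2), ProteinRecord("B", s2 + s3),
                ProteinRecord("C", s3 + s4)]
        assert global_identity(recs[0], recs[1]).identity >= 0.30
        assert global_identity(recs[1], recs[2]).identity >= 0.30
        assert global_identity(recs[0], recs[2]).identity < 0.30
        labels = {r.id: LocalizationLabel.CYTOPLASMIC for r in recs}
        assign = homology_partition(recs, labels, 3, id_thr=0.30, seed=0)
        folds = {assign.folds[i] for i in "ABC"}
        assert len(folds) == 1

    def test_no_cross_fold_homology(self, homolog_fixture):
        records, labels = homolog_fixture
        assign = homology_partition(records, labels, (0.7, 0.15, 0.15),
                                    id_thr=0.30, seed=1)
        assert cross_fold_violations(records, assign, 0.30) == []

    def test_unlabeled_record_rejected(self, rng):
        recs = [ProteinRecord("a", random_seq(rng, 30))]
        with pytest.raises(ValueError):
            homology_partition(recs, {}, 3)

    def test_prefilter_keeps_thresholded_edges(self, homolog_fixture):
        # the 5-mer prefilter may only discard below-threshold pairs
        records, _ = homolog_fixture
        with_pf = identity_edges(records, 0.30, prefilter=True)
        without_pf = identity_edges(records, 0.30, prefilter=False)
        key = lambda e: (e.idA, e.idB)
        assert sorted(map(key, with_pf)) == sorted(map(key, without_pf))


class TestSmote:
    def make_data(self, rng, n_major=40, n_minor=10, dim=5):
        X = np.vstack([rng.normal(0, 1, (n_major, dim)),
                       rng.normal(3, 1, (n_minor, dim))])
        y = np.array([0] * n_major + [1] * n_minor)
        return X, y

    def test_balanced_input_unchanged(self, rng):
        X = rng.normal(size=(20, 4))
        y = np.array([0] * 10 + [1] * 10)
        X2, y2 = smote_oversample(X, y, seed=0)
        assert np.array_equal(X2, X) and np.array_equal(y2, y)

    def test_counts_equalized_and_originals_kept(self, rng):
        X, y = self.make_data(rng)
        X2, y2 = smote_oversample(X, y, seed=0)
        assert (y2 == 0).sum() == (y2 == 1).sum() == 40
        assert np.array_equal(X2[:50], X)

    def test_duplicated_point_yields_itself(self):
        X = np.vstack([np.zeros((10, 3)), np.ones((4, 3))])
        y = np.array([0] * 10 + [1] * 4)
        X2, y2 = smote_oversample(X, y, k=3, seed=0)
        assert np.allclose(X2[y2 == 1], 1.0)

    def test_synthetic_rows_componentwise_between_class_points(self, rng):
        X, y = self.make_data(rng)
        X2, y2 = smote_oversample(X, y, seed=0)
        minority = X[y == 1]
        lo, hi = minority.min(axis=0), minority.max(axis=0)
        synth = X2[len(X):]
        assert np.all(synth >= lo - 1e-12) and np.all(synth <= hi + 1e-12)

    def test_reproducible(self, rng):
        X, y = self.make_data(rng)
        a = smote_oversample(X, y, seed=7)
        b = smote_oversample(X, y, seed=7)
        assert np.array_equal(a[0], b[0])

    def test_tiny_minority_rejected(self, rng):
        X = rng.normal(size=(11, 3))
        y = np.array([0] * 10 + [1])
        with pytest.raises(ValueError):
            smote_oversample(X, y, seed=0)
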