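"""k-mer discriminant, exact genome placement and locus merging."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pirliver.discovery import (
    KmerDiscriminant,
    _shuffle_seq,
    build_loci,
    map_candidates,
    merge_intervals,
    score_pirna_like,
)
from pirliver.simulate import pirna_like_seqs, random_seq
from pirliver.util import revcomp


def _pool(seqs, counts=None, samples=("s1",)):
    data = {s: (counts if counts is not None else [1] * len(seqs)) for s in samples}
    df = pd.DataFrame(data, index=pd.Index(seqs, name="sequence"))
    return df


class TestDiscriminant:
    @pytest.fixture(scope="class")
    @staticmethod
    def training():
        rng = np.random.default_rng(2)
        pos = pirna_like_seqs(rng, 500, u1_prob=0.8)
        neg = [_shuffle_seq(rng, s) for s in pos]
        return pos, neg

    def test_separates_positives_from_shuffles(self, training):
        """Held-out ranking of piRNA-like vs shuffled sequences, AUC > 0.8."""
        from sklearn.metrics import roc_auc_score

        pos, neg = training
        train = pos[:250] + neg[:250]
        disc = KmerDiscriminant(random_state=0).fit(train, [1] * 250 + [0] * 250)
        held = pos[250:] + neg[250:]
        scores = disc.score_sequences(held)
        assert roc_auc_score([1] * 250 + [0] * 250, scores) > 0.8

    def test_training_positive_scores_above_threshold(self, training):
        pos, neg = training
        disc = KmerDiscriminant(random_state=0).fit(
            pos[:200] + neg[:200], [1] * 200 + [0] * 200
        )
        assert disc.score_sequences([pos[0]])[0] >= 0.5

    def test_deterministic_given_seed(self, training):
        pos, neg = training
        pool = _pool(pos[400:450])
        out1, _ = score_pirna_like(pool, pos[:200], neg[:200], seed=5)
        out2, _ = score_pirna_like(pool, pos[:200], neg[:200], seed=5)
        pd.testing.assert_frame_equal(out1, out2)

    def test_training_set_too_small_raises(self):
        with pytest.raises(ValueError, match="training"):
            KmerDiscriminant(min_training=20).fit(["ACGT" * 7] * 5, [1, 1, 0, 0, 0])

    def test_length_window_filters_pool(self, training):
        pos, neg = training
        pool = _pool(["ACGT" * 6, "ACGT" * 7])  # 24 nt and 28 nt
        retained, report = score_pirna_like(
            pool, pos[:100], neg[:100], seed=0, threshold=0.0
        )
        assert report["n_outside_window"] == 1
        assert list(retained.index) == ["ACGT" * 7]


class TestMapCandidates:
    def test_planted_candidate_found_once(self):
        rng = np.random.default_rng(3)
        genome = {"chr1": random_seq(rng, 5000)}
        cand = pirna_like_seqs(rng, 1, 0.8)[0]
        genome["chr1"] = genome["chr1"][:1000] + cand + genome["chr1"][1000:]
        aln, unmapped, rep = map_candidates(_pool([cand]), genome)
        assert len(aln) == 1
        row = aln.iloc[0]
        assert (row.contig, row.start, row.end, row.strand) == ("chr1", 1000, 1000 + len(cand), "+")

    def test_palindrome_maps_to_both_strands(self):
        rng = np.random.default_rng(4)
        half = random_seq(rng, 14)
        palindrome = half + revcomp(half)
        genome = {"chr1": random_seq(rng, 2000) + palindrome + random_seq(rng, 2000)}
        aln, _, _ = map_candidates(_pool([palindrome]), genome)
        # brute-force scan of both strands finds the same interval twice
        assert len(aln) == 2
        assert set(aln.strand) == {"+", "-"}
        assert aln.start.nunique() == 1

    def test_absent_candidate_reported_unmapped(self):
        rng = np.random.default_rng(5)
        genome = {"chr1": random_seq(rng, 3000)}
        absent = "T" * 30
        aln, unmapped, _ = map_candidates(_pool([absent]), genome)
        assert len(aln) == 0 and unmapped == [absent]

    def test_repetitive_candidate_dropped(self):
        seq = "ACGTTGCAACGTTGCAACGTTGCAA"[:25]
        genome = {"chr1": ("X" * 10).replace("X", seq)}  # 10 tandem copies
        aln, _, rep = map_candidates(_pool([seq]), genome, max_placements=5)
        assert rep == [seq]
        assert len(aln) == 0


class TestBuildLoci:
    def _aln(self, rows):
        return pd.DataFrame(rows, columns=["sequence", "contig", "start", "end", "strand"])

    def test_overlap_merges(self):
        aln = self._aln([("a" * 30, "c1", 100, 130, "+"), ("b" * 30, "c1", 120, 150, "+")])
        pool = _pool(["a" * 30, "b" * 30], counts=[2, 3])
        loci, cov = build_loci(aln, pool)
        assert len(loci) == 1
        assert (loci.iloc[0].start, loci.iloc[0].end) == (100, 150)
        assert cov.iloc[0, 0] == 5

    def test_strands_kept_separate(self):
        aln = self._aln([("a" * 30, "c1", 100, 130, "+"), ("b" * 30, "c1", 100, 130, "-")])
        loci, _ = build_loci(aln, _pool(["a" * 30, "b" * 30]))
        assert len(loci) == 2

    def test_merge_distance(self):
        rows = [("a" * 30, "c1", 100, 130, "+"), ("b" * 30, "c1", 131, 160, "+")]
        pool = _pool(["a" * 30, "b" * 30])
        loci0, _ = build_loci(self._aln(rows), pool, merge_distance=0)
        assert len(loci0) == 2
        loci5, _ = build_loci(self._aln(rows), pool, merge_distance=5)
        assert len(loci5) == 1
        assert (loci5.iloc[0].start, loci5.iloc[0].end) == (100, 160)

    def test_negative_merge_distance_rejected(self):
        with pytest.raises(ValueError):
            build_loci(self._aln([]), _pool([]), merge_distance=-1)

    def test_locus_ids_in_genomic_order(self):
        aln = self._aln([("a" * 30, "c2", 10, 40, "+"), ("b" * 30, "c1", 500, 530, "-")])
        loci, _ = build_loci(aln, _pool(["a" * 30, "b" * 30]))
        assert list(loci.locus_id) == ["piR_LLi_1", "piR_LLi_2"]
        assert list(loci.contig) == ["c1", "c2"]

    def test_coverage_conservation_single_mapping(self):
        rng = np.random.default_rng(8)
        seqs = pirna_like_seqs(rng, 20, 0.8)
        genome = {"chr1": "".join(
            random_seq(rng, 50) + s for s in seqs) + random_seq(rng, 50)}
        counts = list(rng.integers(1, 20, len(seqs)))
        pool = _pool(seqs, counts=counts)
        aln, unmapped, _ = map_candidates(pool, genome)
        mapped = [s for s in seqs if s not in unmapped]
        loci, cov = build_loci(aln, pool)
        assert cov.to_numpy().sum() == pool.loc[mapped, "s1"].sum()

    def test_multimap_counts_in_every_locus(self):
        seq = "ACGTACGTTGACCAGGATTACAGGC"
        aln = self._aln([(seq, "c1", 100, 125, "+"), (seq, "c1", 5000, 5025, "+")])
        loci, cov = build_loci(aln, _pool([seq], counts=[7]))
        assert len(loci) == 2
        assert list(cov["s1"]) == [7, 7]
        assert (loci.multimap_fraction == 1.0).all()


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    st.lists(
        st.tuples(st.integers(0, 500), st.integers(1, 60)).map(lambda t: (t[0], t[0] + t[1])),
        max_size=20,
    ),
    st.integers(0, 10),
)
def test_merging_is_idempotent(intervals, merge_distance):
    once = merge_intervals(intervals, merge_distance)
    twice = merge_intervals(once, merge_distance)
    assert once == twice
    assert all(s < e for s, e in once)
    # pairwise disjoint with gaps wider than merge_distance
    for (s1, e1), (s2, e2) in zip(once, once[1:]):
        assert s2 - e1 > merge_distance
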