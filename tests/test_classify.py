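import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from minicirc._align import Aligner, Scoring, align_pair
from minicirc.classify import (
    ClassifierConfig,
    align_read_to_refs,
    filter_hits,
    length_distribution,
    resolve_read_overlaps,
)
from minicirc.core import AlignmentHit, ReadRecord
from minicirc.seq import revcomp
from oracles import sw_oracle


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestAlignReadToRefs:
    def test_identical_read_full_hit(self):
        rng = np.random.default_rng(0)
        ref = _random_seq(rng, 400)
        hits = align_read_to_refs(ReadRecord("r", ref), [("ref", ref)])
        assert len(hits) == 1
        h = hits[0]
        assert h.strand == "+"
        assert h.identity == 1.0
        assert (h.read_start, h.read_end) == (0, 400)
        assert (h.ref_start, h.ref_end) == (0, 400)

    def test_reverse_complement_hit(self):
        rng = np.random.default_rng(1)
        ref = _random_seq(rng, 350)
        hits = align_read_to_refs(ReadRecord("r", revcomp(ref)), [("ref", ref)])
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert hits[0].identity == 1.0
        assert (hits[0].read_start, hits[0].read_end) == (0, 350)

    def test_ten_substitutions_identity_matches_oracle(self):
        rng = np.random.default_rng(2)
        ref = _random_seq(rng, 1000)
        read = list(ref)
        for pos in rng.choice(1000, size=10, replace=False):
            read[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[pos]]
        read = "".join(read)
        hits = align_read_to_refs(ReadRecord("r", read), [("ref", ref)])
        top = max(hits, key=lambda h: h.score)
        oracle = sw_oracle(read, ref)
        assert top.score == oracle[0]
        assert top.identity == pytest.approx(oracle[5] / oracle[6])
        assert top.identity == pytest.approx(0.990, abs=1e-9)

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            align_read_to_refs(ReadRecord("r", "ACGTX"), [("ref", "ACGT" * 20)])

    def test_oracle_equivalence_on_random_pairs(self):
        rng = np.random.default_rng(3)
        scoring = Scoring()
        for _ in range(40):
            a = _random_seq(rng, int(rng.integers(50, 300)))
            b = _random_seq(rng, int(rng.integers(50, 300)))
            aligner = Aligner([("ref", b)], scoring=scoring, min_score=1)
            hits = [h for h in aligner.align(a, floor=1) if h.strand == "+"]
            oracle = sw_oracle(a, b)
            if oracle is None:
                continue
            top = max(hits, key=lambda h: h.score)
            assert top.score == oracle[0]
            assert top.identity == pytest.approx(oracle[5] / oracle[6])

    def test_seeded_path_matches_exact_path(self):
        # force seeding by shrinking exact_max_cells; same hits either way
        rng = np.random.default_rng(4)
        ref = _random_seq(rng, 800)
        read = _random_seq(rng, 500) + ref[50:750] + _random_seq(rng, 500)
        exact = Aligner([("ref", ref)], exact_max_cells=10**9).align(read)
        seeded = Aligner([("ref", ref)], exact_max_cells=0).align(read)
        assert [
            (h.read_start, h.read_end, h.score) for h in exact if h.strand == "+"
        ] == [(h.read_start, h.read_end, h.score) for h in seeded if h.strand == "+"]

    def test_multiple_nonoverlapping_hits_recovered(self):
        rng = np.random.default_rng(5)
        ref = _random_seq(rng, 300)
        spacer = _random_seq(rng, 200)
        read = ref + spacer + ref
        hits = [
            h
            for h in align_read_to_refs(ReadRecord("r", read), [("ref", ref)])
            if h.strand == "+"
        ]
        assert len(hits) == 2
        assert {(h.read_start, h.read_end) for h in hits} == {(0, 300), (500, 800)}


class TestFilterHits:
    @staticmethod
    def _hit(identity=0.95, ref_start=0, ref_end=800, read_span=800, ref_id="g"):
        return AlignmentHit(
            read_id="r",
            ref_id=ref_id,
            read_start=0,
            read_end=read_span,
            ref_start=ref_start,
            ref_end=ref_end,
            strand="+",
            identity=identity,
            score=100,
        )

    REFS = {"g": "A" * 1000}

    def test_strict_removes_identity_below_090(self):
        hits = [self._hit(identity=0.89)]
        assert filter_hits(hits, self.REFS, mode="strict") == []
        assert filter_hits(hits, self.REFS, mode="collect") == hits

    def test_strict_requires_80pct_cds_coverage(self):
        short = self._hit(identity=0.95, ref_start=0, ref_end=790)
        assert filter_hits([short], self.REFS, mode="strict") == []
        assert filter_hits([short], self.REFS, mode="collect") == [short]

    def test_collect_threshold(self):
        low = self._hit(identity=0.79)
        ok = self._hit(identity=0.80)
        assert filter_hits([low, ok], self.REFS, mode="collect") == [ok]

    def test_intron_rich_uses_hit_length(self):
        long_hit = self._hit(identity=0.95, ref_start=0, ref_end=250, read_span=250)
        short_hit = self._hit(identity=0.95, ref_start=0, ref_end=150, read_span=150)
        assert filter_hits([long_hit, short_hit], self.REFS, mode="intron_rich") == [
            long_hit
        ]

    def test_empty_input(self):
        assert filter_hits([], self.REFS, mode="strict") == []

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            filter_hits([], self.REFS, mode="bogus")

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(0.5, 1.0),
                st.integers(0, 500),
                st.integers(501, 1000),
            ),
            max_size=20,
        ),
        st.floats(0.5, 1.0),
        st.floats(0.55, 1.0),
    )
    def test_monotonicity_raising_thresholds(self, raw, thr_lo, thr_hi):
        hits = [
            self._hit(identity=round(i, 3), ref_start=a, ref_end=b)
            for i, a, b in raw
        ]
        lo = min(thr_lo, thr_hi)
        hi = max(thr_lo, thr_hi)
        cfg_lo = ClassifierConfig(min_identity_strict=lo)
        cfg_hi = ClassifierConfig(min_identity_strict=hi)
        kept_lo = filter_hits(hits, self.REFS, cfg_lo, mode="strict")
        kept_hi = filter_hits(hits, self.REFS, cfg_hi, mode="strict")
        assert len(kept_hi) <= len(kept_lo)
        assert set(map(id, kept_hi)) <= set(map(id, kept_lo))


class TestResolveOverlaps:
    def _hit(self, start, end, score, ref_id="g"):
        return AlignmentHit("r", ref_id, start, end, 0, end - start, "+", 0.9, score)

    def test_greedy_by_score(self):
        big = self._hit(0, 500, 900)
        small = self._hit(100, 400, 300, ref_id="h")
        assert resolve_read_overlaps([small, big]) == [big]

    def test_small_overlap_tolerated(self):
        a = self._hit(0, 500, 900)
        b = self._hit(485, 900, 700, ref_id="h")
        assert resolve_read_overlaps([a, b]) == [a, b]


class TestLengthDistribution:
    @staticmethod
    def _strict_hit(read_id, gene):
        return AlignmentHit(read_id, gene, 0, 100, 0, 100, "+", 0.95, 200)

    def test_degenerate_lengths_mode_exact(self):
        reads = [ReadRecord(f"r{i}", "A" * 1234) for i in range(20)]
        hits = [self._strict_hit(r.read_id, "cox1") for r in reads]
        dists = length_distribution(reads, hits)
        assert dists["cox1"].modal_length == 1234.0

    def test_generator_recovery_sigma5(self, circles, cds_refs):
        from minicirc.synthetic import SimulationParams, simulate_reads

        params = SimulationParams(n_reads=2000, length_sigma_rel=0.05, seed=31)
        reads, truth = simulate_reads(circles, params)
        gene_of = dict(zip(truth["read_id"], truth["genes"]))
        hits = [self._strict_hit(r.read_id, gene_of[r.read_id]) for r in reads]
        dists = length_distribution(reads, hits, circles)
        for gene, d in dists.items():
            if d.lengths.size < 50:
                continue
            assert d.mode_relative_error is not None
            # within one bin of the circle length
            assert abs(d.modal_length - d.circle_length) <= 50 + 1e-9

    def test_background_reads_excluded(self):
        reads = [ReadRecord("bg", "A" * 500), ReadRecord("mito", "A" * 900)]
        hits = [self._strict_hit("mito", "cob")]
        dists = length_distribution(reads, hits)
        assert list(dists) == ["cob"]
        assert dists["cob"].lengths.tolist() == [900.0]

    def test_gene_with_zero_reads_flagged_empty(self, circles):
        reads = [ReadRecord("r0", "A" * 100)]
        dists = length_distribution(reads, [], circles)
        assert all(d.empty for d in dists.values())
        assert len(dists) == len({c.gene for c in circles})


class TestStrandInvariance:
    def test_category_counts_unchanged_under_revcomp(
        self, clean_sim, cds_refs, constant_refs
    ):
        from minicirc.classify import ClassifierConfig
        from minicirc.pipeline import classify_read_set

        reads, _ = clean_sim
        subset = reads[:25]
        flipped = [
            ReadRecord(r.read_id, revcomp(r.sequence), r.quality) for r in subset
        ]
        _, fwd = classify_read_set(subset, cds_refs, constant_refs)
        _, rev = classify_read_set(flipped, cds_refs, constant_refs)
        count = lambda cs: sorted(c.category for c in cs)
        assert count(fwd) == count(rev)
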