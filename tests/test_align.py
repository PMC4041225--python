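"""Pairwise alignment, similarity, placement, pre-clustering, k-NN assignment."""

from __future__ import annotations

import functools
import random
from itertools import groupby

import pytest

from itsclade.align import (
    AlignError,
    AlignedRead,
    FilterParams,
    KmerIndex,
    PreclusterParams,
    ScoringScheme,
    column_differences,
    coverage_filter,
    dereplicate,
    knn_classify,
    needleman_align,
    place_read,
    precluster,
    similarity,
    similarity_filter,
)
from itsclade.readqc import Read
from itsclade.refdb import ReferenceDB, ReferenceRecord, trim_to_region

from conftest import taxon

SC = ScoringScheme()


# ---------------------------------------------------------------------------
# independent oracles


def oracle_score(a: str, b: str, sc: ScoringScheme = SC) -> int:
    """Exhaustive optimum via memoized three-state recursion over all
    alignments, with free terminal gaps; independent of the DP matrices."""
    n, m = len(a), len(b)

    @functools.lru_cache(maxsize=None)
    def rec(i: int, j: int, state: str) -> int:
        if i == n or j == m:  # trailing terminal gap: free
            return 0
        s = sc.match if a[i] == b[j] else sc.mismatch
        best = s + rec(i + 1, j + 1, "M")
        cost = sc.gap_extend if state == "E" else sc.gap_open
        best = max(best, cost + rec(i, j + 1, "E"))
        cost = sc.gap_extend if state == "F" else sc.gap_open
        best = max(best, cost + rec(i + 1, j, "F"))
        return best

    best = max(rec(i, 0, "M") for i in range(n + 1))  # free leading gap in b
    return max(best, max(rec(0, j, "M") for j in range(m + 1)))


def oracle_rescore(aligned_a: str, aligned_b: str, sc: ScoringScheme = SC) -> int:
    """Score a returned alignment from its gapped strings alone."""
    L = len(aligned_a)
    terminal: set[int] = set()
    for s in (aligned_a, aligned_b):
        k = 0
        while k < L and s[k] == "-":
            terminal.add(k)
            k += 1
        k = L - 1
        while k >= 0 and s[k] == "-":
            terminal.add(k)
            k -= 1
    score = 0
    gap_a = gap_b = False
    for c in range(L):
        x, y = aligned_a[c], aligned_b[c]
        if c in terminal:
            gap_a, gap_b = x == "-", y == "-"
            continue
        if x == "-":
            score += sc.gap_extend if gap_a else sc.gap_open
            gap_a, gap_b = True, False
        elif y == "-":
            score += sc.gap_extend if gap_b else sc.gap_open
            gap_a, gap_b = False, True
        else:
            score += sc.match if x == y else sc.mismatch
            gap_a = gap_b = False
    return score


def oracle_similarity(a: str, b: str) -> float:
    """Column walk reformulated via groupby over gap states."""
    cols = [(x, y) for x, y in zip(a, b) if not (x == "-" and y == "-")]
    matches = sum(1 for x, y in cols if "-" not in (x, y) and x == y)
    mismatches = sum(1 for x, y in cols if "-" not in (x, y) and x != y)

    def gap_runs(idx):
        states = ["g" if col[idx] == "-" else "b" for col in cols]
        return sum(1 for s, _ in groupby(states) if s == "g")

    denom = matches + mismatches + gap_runs(0) + gap_runs(1)
    return 100.0 * matches / denom


# ---------------------------------------------------------------------------
# needleman_align


class TestNeedlemanAlign:
    def test_identity(self):
        aln = needleman_align("ACGT", "ACGT")
        assert aln.aligned_a == aln.aligned_b == "ACGT"
        assert aln.score == 4

    def test_single_gap(self):
        aln = needleman_align("ACGT", "AGT")
        assert aln.score == 3 - 2  # 3 matches, one gap opening
        assert aln.aligned_a.replace("-", "") == "ACGT"
        assert aln.aligned_b.replace("-", "") == "AGT"
        assert aln.aligned_b.count("-") == 1

    def test_short_read_nests_in_template_for_free(self):
        template = "AAAA" + "CGTCGTACGT" + "TTTT"
        aln = needleman_align("CGTCGTACGT", template)
        assert aln.score == 10  # all matches, terminal gaps free

    def test_empty_input_rejected(self):
        with pytest.raises(AlignError):
            needleman_align("", "ACGT")

    def test_matches_exhaustive_oracle_on_random_pairs(self):
        rng = random.Random(97)
        for _ in range(200):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 12)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 12)))
            res = needleman_align(a, b)
            assert res.score == oracle_score(a, b)
            assert res.aligned_a.replace("-", "") == a
            assert res.aligned_b.replace("-", "") == b
            assert oracle_rescore(res.aligned_a, res.aligned_b) == res.score

    def test_alternative_scoring_still_optimal(self):
        sc = ScoringScheme(match=2, mismatch=-3, gap_open=-4, gap_extend=-1)
        rng = random.Random(98)
        for _ in range(50):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(2, 10)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(2, 10)))
            assert needleman_align(a, b, sc).score == oracle_score(a, b, sc)


# ---------------------------------------------------------------------------
# similarity


class TestSimilarity:
    def test_identical_is_100(self):
        assert similarity("AC-GT", "AC-GT") == 100.0

    def test_18_mismatches_over_180_columns_is_exactly_90(self):
        # the removal rule strikes reads *below* 90%, so 90.0 is kept
        a = "ACGT" * 45
        b = list(a)
        for i in range(18):
            b[10 * i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[10 * i]]
        s = similarity(a, "".join(b))
        assert s == pytest.approx(90.0)
        kept, _ = similarity_filter(
            [_aligned("r", a, sim=s)], FilterParams(min_similarity=90.0)
        )
        assert len(kept) == 1

    def test_gap_run_counts_once(self):
        a = "ACGTACGTAC"
        b = "ACG---GTAC"
        # 7 matching base-base columns plus one 3-column gap run
        assert similarity(a, b) == pytest.approx(100 * 7 / 8)
        assert similarity(a, b, gap_mode="column") == pytest.approx(100 * 7 / 10)

    def test_both_gap_columns_skipped(self):
        assert similarity("A--T", "A--T") == 100.0

    def test_empty_span_rejected(self):
        with pytest.raises(AlignError):
            similarity("--", "--")

    def test_matches_column_walk_oracle_on_random_gapped_pairs(self):
        rng = random.Random(99)
        for _ in range(200):
            length = rng.randint(4, 40)
            a = "".join(rng.choice("ACGT-") for _ in range(length))
            b = "".join(rng.choice("ACGT-") for _ in range(length))
            cols = [
                (x, y) for x, y in zip(a, b) if not (x == "-" and y == "-")
            ]
            if not cols:
                continue
            assert similarity(a, b) == pytest.approx(oracle_similarity(a, b))


# ---------------------------------------------------------------------------
# placement


def _aligned(read_id, seq, sample="s1", template="t", sim=100.0,
             start=None, end=None, abundance=1):
    non_gap = [i for i, ch in enumerate(seq) if ch != "-"]
    return AlignedRead(
        read_id=read_id,
        sample=sample,
        aligned_seq=seq,
        template_id=template,
        similarity=sim,
        start_col=start if start is not None else non_gap[0],
        end_col=end if end is not None else non_gap[-1] + 1,
        abundance=abundance,
    )


@pytest.fixture(scope="module")
def trimmed_reference(request):
    from itsclade.synth import CladeModel, generate_reference

    db, truth, region = generate_reference(CladeModel(seed=2024))
    return trim_to_region(db, region), truth


class TestPlaceRead:
    def test_identity_placement(self, trimmed_reference):
        db, _ = trimmed_reference
        rec = db.records[0]
        placed = place_read(Read("q", rec.ungapped, "s1"), db)
        assert placed.template_id == rec.id
        assert placed.aligned_seq == rec.aligned_seq
        assert placed.similarity == 100.0

    def test_two_substitutions_give_fractional_similarity(self, trimmed_reference):
        db, _ = trimmed_reference
        rec = db.records[0]
        seq = list(rec.ungapped)
        L = len(seq)
        for i in (10, 60):
            seq[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[i]]
        placed = place_read(Read("q", "".join(seq), "s1"), db)
        assert placed.template_id == rec.id
        assert placed.similarity == pytest.approx(100 * (L - 2) / L)

    def test_without_own_clade_template_comes_from_another_clade(
        self, trimmed_reference
    ):
        db, truth = trimmed_reference
        rec = db.records[0]
        clade = rec.taxonomy.clade
        others = db.subset([r.id for r in db.records if truth[r.id] != clade])
        placed = place_read(Read("q", rec.ungapped, "s1"), others)
        assert truth[placed.template_id] != clade
        assert placed.similarity < 100.0

    def test_oversized_read_rejected(self, trimmed_reference):
        db, _ = trimmed_reference
        seq = db.records[0].ungapped * 2
        with pytest.raises(AlignError, match="off-target"):
            place_read(Read("q", seq, "s1"), db)


class TestCoverageFilter:
    def test_full_span_kept_partial_removed(self):
        full = _aligned("full", "ACGTACGTAC")
        short = _aligned("short", "---TACGTAC")
        kept, removed = coverage_filter([full, short], region_width=10)
        assert [r.read_id for r in kept] == ["full"]
        assert [r.read_id for r in removed] == ["short"]

    def test_mixed_fixture_counts(self):
        reads = [
            _aligned(f"f{i}", "ACGTACGTAC") for i in range(6)
        ] + [
            _aligned("s0", "--GTACGTAC"),
            _aligned("s1", "ACGTACGT--"),
            _aligned("s2", "-CGTACGTA-"),
            _aligned("s3", "ACGTACGTA-"),
        ]
        kept, removed = coverage_filter(reads, 10)
        assert len(kept) == 6 and len(removed) == 4


# ---------------------------------------------------------------------------
# dereplication + precluster


class TestPrecluster:
    def test_greedy_merge_within_diffs(self):
        a = _aligned("a", "ACGTACGTAC", abundance=10)
        b_seq = "ACGTACGTAC"
        b_seq = "TCGTACGTAT"[:1] + b_seq[1:5] + "T" + b_seq[6:9] + "G"  # 3 diffs
        b = _aligned("b", b_seq, abundance=2)
        assert column_differences(a.aligned_seq, b.aligned_seq) == 3
        out = precluster([a, b], PreclusterParams(diffs=4))
        assert len(out) == 1
        assert out[0].read_id == "a" and out[0].abundance == 12

    def test_five_differences_stay_separate(self):
        a = _aligned("a", "ACGTACGTAC", abundance=5)
        b = _aligned("b", "TGGTATGTCA", abundance=3)
        assert column_differences(a.aligned_seq, b.aligned_seq) == 5
        out = precluster([a, b], PreclusterParams(diffs=4))
        assert len(out) == 2

    def test_abundance_conserved_on_random_inputs(self):
        rng = random.Random(3)
        reads = []
        for i in range(40):
            seq = "".join(rng.choice("ACGT") for _ in range(30))
            reads.append(_aligned(f"r{i:02d}", seq, abundance=rng.randint(1, 9)))
        unique = dereplicate(reads)
        out = precluster(unique, PreclusterParams(diffs=4))
        assert sum(r.abundance for r in out) == sum(r.abundance for r in reads)

    def test_gap_vs_base_counts_one_both_gap_skipped(self):
        assert column_differences("AC-G--T", "ACCG--T") == 1

    def test_non_dereplicated_input_rejected(self):
        a = _aligned("a", "ACGTACGTAC")
        b = _aligned("b", "ACGTACGTAC")
        with pytest.raises(AlignError, match="dereplicated"):
            precluster([a, b])

    def test_dereplicate_merges_identical_and_sums(self):
        reads = [
            _aligned("r2", "ACGTACGTAC"),
            _aligned("r1", "ACGTACGTAC"),
            _aligned("r3", "TTTTACGTAC"),
        ]
        out = dereplicate(reads)
        assert [(r.read_id, r.abundance) for r in out] == [
            ("r1", 2), ("r3", 1)
        ]

    def test_never_merges_across_clades_on_default_fixture(self, trimmed_reference):
        # clades are >=10% apart while diffs=4 tolerates ~2% of the region,
        # so pre-clustering cannot join reads of different source clades
        db, truth = trimmed_reference
        reads = [
            _aligned(rec.id, rec.aligned_seq, abundance=1 + (i % 3))
            for i, rec in enumerate(db.records)
        ]
        out = precluster(dereplicate(reads), PreclusterParams(diffs=4))
        merged_into: dict[str, list[str]] = {}
        total = sum(r.abundance for r in reads)
        assert sum(r.abundance for r in out) == total
        # every seed's absorbed members must share its clade: reconstruct by
        # replaying the greedy walk
        ordered = sorted(
            dereplicate(reads), key=lambda r: (-r.abundance, r.read_id)
        )
        seeds: list[AlignedRead] = []
        for r in ordered:
            for seed in seeds:
                if column_differences(r.aligned_seq, seed.aligned_seq) <= 4:
                    assert truth[r.read_id] == truth[seed.read_id]
                    break
            else:
                seeds.append(r)


# ---------------------------------------------------------------------------
# knn classification


class TestKnnClassify:
    def test_identical_read_gets_reference_taxonomy(self, trimmed_reference):
        db, truth = trimmed_reference
        rec = db.records[5]
        read = _aligned("q", rec.aligned_seq)
        a = knn_classify(read, db)
        assert a.nearest_ref == rec.id
        assert a.taxonomy == rec.taxonomy
        assert a.similarity == 100.0
        assert a.method == "knn, k=1"

    def test_constructed_margin_assigns_correct_clade(self):
        width = 40
        base = "ACGTACGTAC" * 4
        far = "TGCATGCATG" * 4
        db = ReferenceDB(
            [
                ReferenceRecord("iv_ref", base, taxon("IV")),
                ReferenceRecord("ii_ref", far, taxon("II")),
            ],
            width,
        )
        q = list(base)
        q[3] = "T" if q[3] != "T" else "A"
        q[17] = "T" if q[17] != "T" else "A"
        a = knn_classify(_aligned("q", "".join(q)), db)
        assert a.taxonomy.clade == "IV" and a.nearest_ref == "iv_ref"

    def test_tie_between_same_clade_references_is_harmless(self):
        seq = "ACGTACGTAC"
        db = ReferenceDB(
            [
                ReferenceRecord("b_ref", seq, taxon("II")),
                ReferenceRecord("a_ref", seq, taxon("II")),
            ],
            10,
        )
        a = knn_classify(_aligned("q", seq), db)
        assert a.taxonomy.clade == "II"
        assert a.nearest_ref == "a_ref"  # deterministic id tie-break

    def test_nearest_really_is_nearest_exhaustively(self, trimmed_reference):
        db, _ = trimmed_reference
        small = db.subset(db.ids[:12])
        rec = small.records[7]
        seq = list(rec.ungapped)
        seq[5] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[5]]
        placed = place_read(Read("q", "".join(seq), "s1"), small)
        a = knn_classify(placed, small)
        span = (placed.start_col, placed.end_col)
        for ref in small.records:
            assert a.similarity >= similarity(
                placed.aligned_seq, ref.aligned_seq, span
            )

    def test_empty_db_rejected(self):
        with pytest.raises(AlignError):
            knn_classify(_aligned("q", "ACGT"), ReferenceDB([], 0))
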