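"""Template-based read placement and nearest-neighbour clade assignment.

Reads are placed into reference alignment coordinates in the style of
template-based aligners: the candidate template is the reference sharing
the most 8-mers with the read; the read is then globally aligned to the
ungapped template with a Needleman-Wunsch algorithm under affine gap
scoring with free terminal gaps (semi-global), and the read's bases are
projected into the template's alignment columns.  Read insertions relative
to the template cannot be represented in fixed reference coordinates and
are dropped (counted per read).

Similarity between two gapped sequences counts each maximal run of gap
columns in one sequence as ONE difference ("onegap" counting); columns
gapped in both sequences are skipped.  Reads below 90% similarity to their
template, or not covering the full alignment span, are removed before
classification.  Near-identical reads are then pre-clustered (greedy,
abundance-ranked, column-difference threshold diffs=4) to absorb
pyrosequencing errors, and each surviving sequence receives the four-rank
taxonomy of its single most similar reference (k-nearest neighbour, k=1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from itsclade.readqc import Read
from itsclade.refdb import ReferenceDB, TaxonomyPath

logger = logging.getLogger(__name__)

NEG_INF = -(10**9)


class AlignError(ValueError):
    pass


# ---------------------------------------------------------------------------
# pairwise alignment


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: int


@dataclass(frozen=True)
class ScoringScheme:
    """Affine gap scoring; a length-L gap run costs open + (L-1)*extend.

    Terminal gap runs in either sequence are free, so a short read nests
    inside a longer template without penalty.
    """

    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1


DEFAULT_SCORING = ScoringScheme()


def needleman_align(
    a: str, b: str, scoring: ScoringScheme = DEFAULT_SCORING
) -> PairwiseAlignment:
    """Optimal global alignment of two sequences, terminal gaps free.

    Three-state affine-gap dynamic programming (match/mismatch, gap-in-a,
    gap-in-b); the best score over the last row and column is extended with
    unpenalised terminal gaps.  Ties in the traceback resolve
    diagonal-first, then gap-in-b (consuming ``a``), for determinism.
    """
    if not a or not b:
        raise AlignError("cannot align empty sequences")
    a, b = a.upper(), b.upper()
    n, m = len(a), len(b)
    go, ge = scoring.gap_open, scoring.gap_extend

    a_arr = np.frombuffer(a.encode(), dtype=np.uint8)
    b_arr = np.frombuffer(b.encode(), dtype=np.uint8)

    # M: a[i-1] aligned to b[j-1]; E: gap in a (consumes b); F: gap in b
    M = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)
    M[0, 0] = 0
    E[0, 1:] = 0  # free terminal gap in a
    F[1:, 0] = 0  # free terminal gap in b

    j_idx = np.arange(1, m + 1)
    sub = np.where(a_arr[:, None] == b_arr[None, :], scoring.match, scoring.mismatch)

    H_prev = np.maximum.reduce([M[0], E[0], F[0]])
    for i in range(1, n + 1):
        M[i, 1:] = H_prev[:-1] + sub[i - 1]
        F[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], E[i - 1, 1:]) + go, F[i - 1, 1:] + ge
        )
        # E[i,j] = max over k<j of (max(M,F)[i,k] + go + (j-1-k)*ge),
        # unrolled via a running maximum; E-from-E extension is exactly the
        # ge*(j-1-k) term, so E is not a source here
        G = np.maximum(M[i], F[i])
        run = np.maximum.accumulate(G[:-1] - ge * np.arange(m))
        E[i, 1:] = run + go + ge * (j_idx - 1)
        H_prev = np.maximum.reduce([M[i], E[i], F[i]])

    H = np.maximum.reduce([M, E, F])

    # best end: free terminal gaps mean the optimum ends on the last row or
    # last column; ties prefer the bottom-right-most cell on the last column
    last_col = H[:, m]
    last_row = H[n, :]
    i_best = int(np.argmax(last_col[::-1]))
    i_best = n - i_best
    j_best = int(np.argmax(last_row[::-1]))
    j_best = m - j_best
    if last_col[i_best] >= last_row[j_best]:
        ei, ej = i_best, m
    else:
        ei, ej = n, j_best
    score = int(max(last_col[i_best], last_row[j_best]))

    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    # terminal pad after the end cell
    for k in range(n - 1, ei - 1, -1):
        out_a.append(a[k])
        out_b.append("-")
    for k in range(m - 1, ej - 1, -1):
        out_a.append("-")
        out_b.append(b[k])

    i, j = ei, ej
    state = max(
        (("M", M[i, j]), ("F", F[i, j]), ("E", E[i, j])), key=lambda t: t[1]
    )[0]
    while i > 0 and j > 0:
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
            state = max(
                (("M", M[i, j]), ("F", F[i, j]), ("E", E[i, j])),
                key=lambda t: t[1],
            )[0]
        elif state == "F":  # gap in b, consume a[i-1]
            out_a.append(a[i - 1])
            out_b.append("-")
            if F[i, j] == F[i - 1, j] + ge and F[i - 1, j] > NEG_INF // 2:
                state = "F"
            else:
                state = "M" if M[i - 1, j] >= E[i - 1, j] else "E"
            i -= 1
        else:  # E: gap in a, consume b[j-1]
            out_a.append("-")
            out_b.append(b[j - 1])
            # reconstruct whether the run continues left
            cont = E[i, j - 1] + ge
            src = max(M[i, j - 1], F[i, j - 1]) + go
            if j - 1 > 0 and cont >= src and E[i, j - 1] > NEG_INF // 2:
                state = "E"
            else:
                state = "M" if M[i, j - 1] >= F[i, j - 1] else "F"
            j -= 1
    while i > 0:
        out_a.append(a[i - 1])
        out_b.append("-")
        i -= 1
    while j > 0:
        out_a.append("-")
        out_b.append(b[j - 1])
        j -= 1

    return PairwiseAlignment("".join(reversed(out_a)), "".join(reversed(out_b)), score)


# ---------------------------------------------------------------------------
# similarity over alignment columns


def similarity(
    a_cols: str,
    b_cols: str,
    span: tuple[int, int] | None = None,
    gap_mode: str = "run",
) -> float:
    """Percent identity over alignment columns with gap-run counting.

    Columns gapped in both sequences are skipped.  In ``run`` mode each
    maximal run of gap columns in one sequence counts as one difference
    (mothur's "onegap"); in ``column`` mode every gap column counts.
    similarity = 100 * matches / (matches + mismatches + gap_differences).
    """
    if len(a_cols) != len(b_cols):
        raise AlignError("gapped sequences differ in length")
    if gap_mode not in ("run", "column"):
        raise AlignError(f"unknown gap_mode {gap_mode!r}")
    start, end = span if span is not None else (0, len(a_cols))
    matches = mismatches = gap_diffs = 0
    in_gap_a = in_gap_b = False
    for c in range(start, end):
        x, y = a_cols[c], b_cols[c]
        if x == "-" and y == "-":
            continue
        if x == "-":
            if gap_mode == "column" or not in_gap_a:
                gap_diffs += 1
            in_gap_a, in_gap_b = True, False
        elif y == "-":
            if gap_mode == "column" or not in_gap_b:
                gap_diffs += 1
            in_gap_a, in_gap_b = False, True
        else:
            in_gap_a = in_gap_b = False
            if x == y:
                matches += 1
            else:
                mismatches += 1
    denom = matches + mismatches + gap_diffs
    if denom == 0:
        raise AlignError("no comparable columns in span")
    return 100.0 * matches / denom


# ---------------------------------------------------------------------------
# placement


@dataclass
class AlignedRead:
    """A read projected into reference alignment coordinates."""

    read_id: str
    sample: str
    aligned_seq: str
    template_id: str
    similarity: float
    start_col: int
    end_col: int
    abundance: int = 1
    dropped_insertions: int = 0

    def __post_init__(self) -> None:
        if self.start_col >= self.end_col:
            raise AlignError(
                f"read {self.read_id!r}: empty column span "
                f"[{self.start_col}, {self.end_col})"
            )


@dataclass(frozen=True)
class FilterParams:
    min_similarity: float = 90.0
    require_full_coverage: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.min_similarity <= 100:
            raise AlignError("min_similarity must be in [0, 100]")


@dataclass(frozen=True)
class PreclusterParams:
    diffs: int = 4

    def __post_init__(self) -> None:
        if self.diffs < 0:
            raise AlignError("diffs must be >= 0")


class KmerIndex:
    """Shared-k-mer counting for candidate template selection (k=8)."""

    def __init__(self, db: ReferenceDB, k: int = 8):
        self.k = k
        self.db = db
        self._kmer_sets: list[tuple[str, frozenset[str]]] = []
        for rec in db.records:
            u = rec.ungapped
            kmers = frozenset(u[i : i + k] for i in range(len(u) - k + 1))
            self._kmer_sets.append((rec.id, kmers))

    def best_template(self, read_seq: str) -> str:
        """Reference sharing the most k-mers; ties to smallest id."""
        read_kmers = {
            read_seq[i : i + self.k] for i in range(len(read_seq) - self.k + 1)
        }
        best_id: str | None = None
        best_count = -1
        for ref_id, kmers in sorted(self._kmer_sets):
            c = len(read_kmers & kmers)
            if c > best_count:
                best_count, best_id = c, ref_id
        assert best_id is not None
        return best_id


def _column_map(aligned_seq: str) -> list[int]:
    """Alignment column of each ungapped position."""
    return [c for c, ch in enumerate(aligned_seq) if ch != "-"]


def place_read(
    read: Read,
    db: ReferenceDB,
    index: KmerIndex | None = None,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> AlignedRead:
    """Place a read into the trimmed reference alignment's coordinates.

    Selects the template by shared 8-mer count, aligns read to the ungapped
    template (semi-global NW), projects read bases onto the template's
    alignment columns, and computes the similarity over the placed span.
    Read insertions relative to the template are dropped with a logged
    per-read count.
    """
    if len(db) == 0:
        raise AlignError("empty reference database")
    if index is None:
        index = KmerIndex(db)
    template_id = index.best_template(read.seq)
    template = db[template_id]
    t_ungapped = template.ungapped
    if len(read.seq) > 1.5 * len(t_ungapped):
        raise AlignError(
            f"read {read.id!r} ({len(read.seq)} nt) exceeds template "
            f"{template_id!r} ungapped length + 50% ({len(t_ungapped)} nt): "
            "suspected off-target sequence"
        )
    aln = needleman_align(read.seq, t_ungapped, scoring)

    col_of = _column_map(template.aligned_seq)
    cols = ["-"] * db.n_columns
    t_pos = 0
    dropped = 0
    for rc, tc in zip(aln.aligned_a, aln.aligned_b):
        if tc != "-":
            if rc != "-":
                cols[col_of[t_pos]] = rc
            t_pos += 1
        elif rc != "-":
            dropped += 1  # read insertion: unrepresentable in fixed columns
    if dropped:
        logger.debug("read %s: dropped %d insertion bases", read.id, dropped)

    placed = "".join(cols)
    non_gap = [c for c, ch in enumerate(placed) if ch != "-"]
    if not non_gap:
        raise AlignError(f"read {read.id!r} placed entirely as gaps")
    start_col, end_col = non_gap[0], non_gap[-1] + 1
    sim = similarity(placed, template.aligned_seq, (start_col, end_col))
    return AlignedRead(
        read_id=read.id,
        sample=read.sample or "",
        aligned_seq=placed,
        template_id=template_id,
        similarity=sim,
        start_col=start_col,
        end_col=end_col,
        dropped_insertions=dropped,
    )


def similarity_filter(
    reads: Iterable[AlignedRead], params: FilterParams
) -> tuple[list[AlignedRead], list[AlignedRead]]:
    """Drop reads whose best-template similarity is below the threshold.

    The protocol removes reads with similarity *less than* 90%; a read at
    exactly the threshold is kept.
    """
    kept, removed = [], []
    for r in reads:
        (kept if r.similarity >= params.min_similarity else removed).append(r)
    return kept, removed


def coverage_filter(
    reads: Iterable[AlignedRead], region_width: int
) -> tuple[list[AlignedRead], list[AlignedRead]]:
    """Remove short reads with gaps at the start or end of the alignment."""
    kept, removed = [], []
    for r in reads:
        if r.start_col > 0 or r.end_col < region_width:
            removed.append(r)
        else:
            kept.append(r)
    return kept, removed


# ---------------------------------------------------------------------------
# dereplication and pre-clustering


def dereplicate(reads: Sequence[AlignedRead]) -> list[AlignedRead]:
    """Merge reads with identical aligned sequences, summing abundances.

    The representative is the read with the smallest id; output order is by
    abundance descending, then representative id.
    """
    groups: dict[str, list[AlignedRead]] = {}
    for r in reads:
        groups.setdefault(r.aligned_seq, []).append(r)
    out: list[AlignedRead] = []
    for seq, members in groups.items():
        rep = min(members, key=lambda r: r.read_id)
        out.append(
            replace(rep, abundance=sum(m.abundance for m in members))
        )
    out.sort(key=lambda r: (-r.abundance, r.read_id))
    return out


def column_differences(a_cols: str, b_cols: str) -> int:
    """Column-wise difference count: both-gap skipped, gap-vs-base counts 1."""
    if len(a_cols) != len(b_cols):
        raise AlignError("gapped sequences differ in length")
    return sum(
        1
        for x, y in zip(a_cols, b_cols)
        if not (x == "-" and y == "-") and x != y
    )


def precluster(
    reads: Sequence[AlignedRead], params: PreclusterParams = PreclusterParams()
) -> list[AlignedRead]:
    """Greedy abundance-ranked merging of near-identical sequences.

    Input must be dereplicated.  Unique sequences are visited from most to
    least abundant (ties by id ascending); each is merged into the FIRST
    already-retained seed within ``diffs`` column differences, otherwise it
    becomes a seed itself.  Total abundance is conserved.
    """
    seen = set()
    for r in reads:
        if r.aligned_seq in seen:
            raise AlignError(
                "precluster requires dereplicated input "
                f"(duplicate aligned sequence at read {r.read_id!r})"
            )
        seen.add(r.aligned_seq)
    ordered = sorted(reads, key=lambda r: (-r.abundance, r.read_id))
    seeds: list[AlignedRead] = []
    for r in ordered:
        for idx, seed in enumerate(seeds):
            if column_differences(r.aligned_seq, seed.aligned_seq) <= params.diffs:
                seeds[idx] = replace(seed, abundance=seed.abundance + r.abundance)
                break
        else:
            seeds.append(r)
    return seeds


# ---------------------------------------------------------------------------
# k-nearest-neighbour classification


@dataclass(frozen=True)
class CladeAssignment:
    read_id: str
    sample: str
    taxonomy: TaxonomyPath
    nearest_ref: str
    similarity: float
    abundance: int = 1
    method: str = "knn, k=1"


def knn_classify(
    read: AlignedRead, db: ReferenceDB, k: int = 1
) -> CladeAssignment:
    """Assign the read the taxonomy of its nearest reference (k=1).

    Similarity is computed against every reference over the read's placed
    span; the maximal-similarity reference wins, ties breaking to the
    lexicographically smallest id.  For k>1 a majority vote is taken over
    the k nearest; vote ties collapse to the deepest common ancestor of the
    tied lineages (unresolved ranks are labelled "unclassified").
    """
    if len(db) == 0:
        raise AlignError("empty reference database")
    if k < 1:
        raise AlignError("k must be >= 1")
    span = (read.start_col, read.end_col)
    sims: list[tuple[float, str]] = []
    for rec in db.records:
        try:
            s = similarity(read.aligned_seq, rec.aligned_seq, span)
        except AlignError:
            continue  # reference all-gap over this span
        sims.append((s, rec.id))
    if not sims:
        raise AlignError(f"no reference comparable to read {read.read_id!r}")
    sims.sort(key=lambda t: (-t[0], t[1]))
    best_sim, best_id = sims[0]

    if k == 1:
        taxonomy = db[best_id].taxonomy
    else:
        top = sims[: min(k, len(sims))]
        votes: dict[tuple[str, ...], int] = {}
        for _, rid in top:
            ranks = db[rid].taxonomy.ranks
            votes[ranks] = votes.get(ranks, 0) + 1
        max_votes = max(votes.values())
        winners = [ranks for ranks, v in votes.items() if v == max_votes]
        if len(winners) == 1:
            taxonomy = TaxonomyPath(winners[0])
        else:
            ranks = []
            for level in range(4):
                labels = {w[level] for w in winners}
                ranks.append(labels.pop() if len(labels) == 1 else "unclassified")
            taxonomy = TaxonomyPath(tuple(ranks))  # type: ignore[arg-type]
    return CladeAssignment(
        read_id=read.read_id,
        sample=read.sample,
        taxonomy=taxonomy,
        nearest_ref=best_id,
        similarity=best_sim,
        abundance=read.abundance,
    )
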