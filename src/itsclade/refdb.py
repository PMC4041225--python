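"""Reference database I/O: gapped alignments, four-rank taxonomy, regions.

The classification reference is a uniform-width gapped nucleotide alignment
(full-length 16S-23S ITS sequences) paired with a taxonomy table assigning
each sequence exactly four ranks: domain-level (Cyanobacteria), genus-level
(*Synechococcus* / *Prochlorococcus*), subcluster-level (SC5.1 / SC5.2 /
SC5.3 or HL/LL), and clade-level (I, II, IV, CRD1, UC-A, ...).  Taxonomy
files follow the mothur dialect ``id<TAB>r1;r2;r3;r4;`` (trailing semicolon
accepted and emitted).

For short-amplicon classification the alignment is trimmed to the region
between the forward primer and the tRNA-Ile gene; the highly conserved tRNA
block itself carries no clade signal and is deleted.  All column coordinates
are 0-based, half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

N_RANKS = 4

# alignment alphabet after normalisation: bases, IUPAC ambiguity, gap
_IUPAC = set("ACGTRYSWKMBDHVN")
_VALID_ALIGNED = _IUPAC | {"-"}


class ReferenceError(ValueError):
    """Malformed reference alignment or taxonomy input."""


@dataclass(frozen=True)
class TaxonomyPath:
    """Ordered four-rank lineage: (domain, genus, subcluster, clade)."""

    ranks: tuple[str, str, str, str]

    def __post_init__(self) -> None:
        if len(self.ranks) != N_RANKS:
            raise ReferenceError(
                f"taxonomy must have exactly {N_RANKS} ranks, got {len(self.ranks)}: {self.ranks!r}"
            )
        for r in self.ranks:
            if not r:
                raise ReferenceError(f"empty rank label in {self.ranks!r}")
            if ";" in r:
                raise ReferenceError(f"';' not allowed inside a rank label: {r!r}")
        object.__setattr__(self, "ranks", tuple(self.ranks))

    @classmethod
    def from_string(cls, text: str) -> "TaxonomyPath":
        """Parse ``r1;r2;r3;r4`` (trailing ';' tolerated)."""
        parts = [p.strip() for p in text.strip().rstrip(";").split(";")]
        return cls(tuple(parts))  # type: ignore[arg-type]

    def to_string(self) -> str:
        return ";".join(self.ranks) + ";"

    @property
    def clade(self) -> str:
        return self.ranks[3]

    @property
    def subcluster(self) -> str:
        return self.ranks[2]

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


@dataclass(frozen=True)
class ReferenceRecord:
    id: str
    aligned_seq: str
    taxonomy: TaxonomyPath

    @property
    def ungapped(self) -> str:
        return self.aligned_seq.replace("-", "")


@dataclass(frozen=True)
class RegionSpec:
    """Half-open column window with excluded sub-blocks (e.g. tRNA-Ile).

    ``start_col``/``end_col`` bound the region kept for classification;
    every interval in ``excluded_blocks`` is deleted from within it.
    """

    start_col: int
    end_col: int
    excluded_blocks: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.start_col < self.end_col:
            raise ReferenceError(
                f"invalid region [{self.start_col}, {self.end_col})"
            )
        blocks = tuple(sorted(tuple(b) for b in self.excluded_blocks))
        prev_end = self.start_col
        for s, e in blocks:
            if not (self.start_col <= s < e <= self.end_col):
                raise ReferenceError(
                    f"excluded block [{s}, {e}) outside region "
                    f"[{self.start_col}, {self.end_col})"
                )
            if s < prev_end:
                raise ReferenceError(f"excluded blocks overlap at column {s}")
            prev_end = e
        object.__setattr__(self, "excluded_blocks", blocks)

    @property
    def kept_width(self) -> int:
        return (self.end_col - self.start_col) - sum(
            e - s for s, e in self.excluded_blocks
        )

    def kept_columns(self, n_columns: int | None = None) -> list[int]:
        """Alignment columns retained by the region, in order."""
        if n_columns is not None and self.end_col > n_columns:
            raise ReferenceError(
                f"region end {self.end_col} exceeds alignment width {n_columns}"
            )
        dropped: set[int] = set()
        for s, e in self.excluded_blocks:
            dropped.update(range(s, e))
        return [c for c in range(self.start_col, self.end_col) if c not in dropped]


@dataclass
class ReferenceDB:
    """Uniform-width reference alignment plus taxonomy; the target space."""

    records: list[ReferenceRecord]
    n_columns: int
    region: RegionSpec | None = None
    _by_id: dict[str, ReferenceRecord] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        seen: dict[str, ReferenceRecord] = {}
        for rec in self.records:
            if rec.id in seen:
                raise ReferenceError(f"duplicate reference id {rec.id!r}")
            if len(rec.aligned_seq) != self.n_columns:
                raise ReferenceError(
                    f"record {rec.id!r} has {len(rec.aligned_seq)} columns, "
                    f"alignment width is {self.n_columns}"
                )
            seen[rec.id] = rec
        self._by_id = seen

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, ref_id: str) -> ReferenceRecord:
        return self._by_id[ref_id]

    def __contains__(self, ref_id: str) -> bool:
        return ref_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def clades(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.taxonomy.clade not in out:
                out.append(r.taxonomy.clade)
        return out

    def subset(self, ids: Iterable[str]) -> "ReferenceDB":
        wanted = set(ids)
        return ReferenceDB(
            [r for r in self.records if r.id in wanted], self.n_columns, self.region
        )


def _normalise_aligned(seq: str, rec_id: str) -> str:
    s = seq.upper().replace(".", "-").replace("U", "T")
    bad = set(s) - _VALID_ALIGNED
    if bad:
        raise ReferenceError(
            f"record {rec_id!r} contains non-IUPAC characters: {sorted(bad)}"
        )
    return s


def read_taxonomy(source: Union[str, Path, TextIO]) -> dict[str, TaxonomyPath]:
    """Read a mothur-style taxonomy table: ``id<TAB>r1;r2;r3;r4;`` per line."""
    close = False
    if isinstance(source, (str, Path)):
        handle: TextIO = open(source)
        close = True
    else:
        handle = source
    try:
        out: dict[str, TaxonomyPath] = {}
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line:
                continue
            try:
                rec_id, tax = line.split("\t", 1)
            except ValueError:
                raise ReferenceError(
                    f"taxonomy line {lineno} is not tab-separated: {line!r}"
                ) from None
            if rec_id in out:
                raise ReferenceError(f"duplicate taxonomy id {rec_id!r}")
            out[rec_id] = TaxonomyPath.from_string(tax)
        return out
    finally:
        if close:
            handle.close()


def load_reference(
    alignment_source: Union[str, Path, TextIO],
    taxonomy_source: Union[str, Path, TextIO],
) -> ReferenceDB:
    """Load a gapped FASTA alignment and its taxonomy table into a ReferenceDB.

    Sequences are uppercased, ``.`` gaps normalised to ``-`` and ``U`` mapped
    to ``T``.  Every alignment id must have a taxonomy row and vice versa;
    ragged alignments and taxonomies with a rank count other than four are
    rejected.
    """
    taxonomy = read_taxonomy(taxonomy_source)
    seqs: list[tuple[str, str]] = []
    for rec in SeqIO.parse(alignment_source, "fasta"):
        seqs.append((rec.id, _normalise_aligned(str(rec.seq), rec.id)))
    if not seqs:
        raise ReferenceError("empty reference alignment")

    n_columns = len(seqs[0][1])
    for rec_id, s in seqs:
        if len(s) != n_columns:
            raise ReferenceError(
                f"ragged alignment: record {rec_id!r} has {len(s)} columns, "
                f"expected {n_columns}"
            )

    aln_ids = {i for i, _ in seqs}
    orphan_aln = sorted(aln_ids - set(taxonomy))
    orphan_tax = sorted(set(taxonomy) - aln_ids)
    if orphan_aln or orphan_tax:
        raise ReferenceError(
            "alignment/taxonomy id mismatch; "
            f"alignment-only: {orphan_aln}; taxonomy-only: {orphan_tax}"
        )

    records = [ReferenceRecord(i, s, taxonomy[i]) for i, s in seqs]
    return ReferenceDB(records, n_columns)


def trim_to_region(db: ReferenceDB, region: RegionSpec) -> ReferenceDB:
    """Restrict every record to the region's kept columns.

    Records whose trimmed sequence is all gaps are dropped with a warning.
    The region is stored on the result; its coordinates remain those of the
    original alignment.
    """
    cols = region.kept_columns(db.n_columns)
    trimmed: list[ReferenceRecord] = []
    for rec in db.records:
        seq = "".join(rec.aligned_seq[c] for c in cols)
        if set(seq) <= {"-"}:
            logger.warning(
                "dropping reference %s: all-gap after trimming to region", rec.id
            )
            continue
        trimmed.append(replace(rec, aligned_seq=seq))
    return ReferenceDB(trimmed, len(cols), region)


def export_taxonomy(db: ReferenceDB, sink: Union[str, Path, TextIO]) -> None:
    """Write the taxonomy table in the mothur dialect (trailing ';')."""
    close = False
    if isinstance(sink, (str, Path)):
        handle: TextIO = open(sink, "w")
        close = True
    else:
        handle = sink
    try:
        for rec in db.records:
            handle.write(f"{rec.id}\t{rec.taxonomy.to_string()}\n")
    finally:
        if close:
            handle.close()


def export_alignment(db: ReferenceDB, sink: Union[str, Path, TextIO]) -> None:
    """Write the (possibly trimmed) alignment as gapped FASTA."""
    records = [
        SeqRecord(Seq(r.aligned_seq), id=r.id, description="") for r in db.records
    ]
    SeqIO.write(records, sink, "fasta")


def export_reads_fasta(
    reads: Iterable[tuple[str, str]], sink: Union[str, Path, TextIO]
) -> None:
    """Write (id, sequence) pairs as plain FASTA."""
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in reads]
    SeqIO.write(records, sink, "fasta")


def load_reads_fasta(source: Union[str, Path, TextIO]) -> list[tuple[str, str]]:
    """Read unaligned reads; uppercased, U->T. Gaps are not allowed."""
    out: list[tuple[str, str]] = []
    for rec in SeqIO.parse(source, "fasta"):
        s = str(rec.seq).upper().replace("U", "T")
        if "-" in s or "." in s:
            raise ReferenceError(f"read {rec.id!r} contains gap characters")
        out.append((rec.id, s))
    return out
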