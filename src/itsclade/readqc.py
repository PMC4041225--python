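"""Demultiplexing and quality filtering of multiplexed amplicon reads.

Fusion reads open with key + barcode + forward oligo; a read is assigned to
a sample only on a perfect match of key and barcode and a perfect
(IUPAC-aware) match of the forward oligo, after which those parts are
removed.  Remaining filters: the longest homopolymer run may not exceed 6
(the characteristic 454 error mode) and the read length must fall inside a
configurable window standing in for the original flowgram-space filters.
If the reverse primer's reverse complement is found near-perfectly
(<=1 mismatch) inside the read, the read is truncated there: amplicons
shorter than the read length read through into the reverse primer.

Each read lands in exactly one accounting bin; the first failing check in
the order barcode -> primer -> homopolymer -> length wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby
from typing import Iterable, Iterator

from itsclade.primers import PrimerSpec, iupac_mismatches, reverse_complement


class QCError(ValueError):
    pass


@dataclass
class Read:
    id: str
    seq: str
    sample: str | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise QCError(f"read {self.id!r} has empty sequence")
        self.seq = self.seq.upper()


@dataclass(frozen=True)
class QCParams:
    max_homopolymer: int = 6
    min_length: int = 150
    max_length: int = 450
    # the filtering protocol admits only perfect barcode/forward-primer
    # matches; these switches exist to make that explicit, not to relax it
    require_exact_barcode: bool = True
    require_exact_forward_primer: bool = True

    def __post_init__(self) -> None:
        if self.max_homopolymer < 1:
            raise QCError("max_homopolymer must be >= 1")
        if not 0 <= self.min_length <= self.max_length:
            raise QCError("need 0 <= min_length <= max_length")


@dataclass
class QCSummary:
    """Per-sample and total accounting; input == passed + sum(failures)."""

    input: int = 0
    failed_barcode: int = 0
    failed_primer: int = 0
    failed_homopolymer: int = 0
    failed_length: int = 0
    passed: int = 0
    per_sample: dict[str, dict[str, int]] = field(default_factory=dict)

    _BINS = ("input", "failed_primer", "failed_homopolymer", "failed_length", "passed")

    def _sample(self, sample: str) -> dict[str, int]:
        return self.per_sample.setdefault(sample, {b: 0 for b in self._BINS})

    def tally(self, bin_name: str, sample: str | None = None) -> None:
        setattr(self, bin_name, getattr(self, bin_name) + 1)
        if sample is not None:
            self._sample(sample)[bin_name] += 1

    def check_conservation(self) -> bool:
        return self.input == (
            self.passed
            + self.failed_barcode
            + self.failed_primer
            + self.failed_homopolymer
            + self.failed_length
        )


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest run of a single repeated base."""
    if not seq:
        raise QCError("empty sequence")
    return max(sum(1 for _ in run) for _, run in groupby(seq))


def trim_reverse_primer(seq: str, rev_oligo: str, max_mismatch: int = 1) -> str:
    """Cut the read at the reverse primer's reverse-complement site.

    The rightmost full window with <= max_mismatch IUPAC mismatches is used;
    reads that do not reach the reverse primer are returned unchanged.
    """
    probe = reverse_complement(rev_oligo.upper())
    k = len(probe)
    if len(seq) < k:
        return seq
    for pos in range(len(seq) - k, -1, -1):
        if iupac_mismatches(probe, seq[pos : pos + k]) <= max_mismatch:
            return seq[:pos]
    return seq


def demultiplex(
    reads: Iterable[Read],
    barcodes: dict[str, str],
    key: str,
    fwd_oligo: str,
    rev_oligo: str | None = None,
) -> tuple[dict[str, list[Read]], QCSummary]:
    """Assign reads to samples by exact key+barcode and perfect forward oligo.

    ``barcodes`` maps barcode sequence -> sample name.  Assigned reads have
    key, barcode and forward primer removed (and, when ``rev_oligo`` is
    given, the read-through reverse primer trimmed from the 3' end).
    Returns per-sample read lists plus a partial QCSummary covering the
    barcode/primer bins.
    """
    if not barcodes:
        raise QCError("empty barcode map")
    lengths = {len(b) for b in barcodes}
    if len(lengths) != 1:
        raise QCError("barcodes must all have the same length")
    if len(set(barcodes.values())) != len(barcodes):
        raise QCError("two barcodes map to the same sample")
    bc_len = next(iter(lengths))
    key = key.upper()
    fwd = fwd_oligo.upper()
    norm_barcodes = {b.upper(): s for b, s in barcodes.items()}
    if len(norm_barcodes) != len(barcodes):
        raise QCError("duplicate barcode")

    by_sample: dict[str, list[Read]] = {s: [] for s in barcodes.values()}
    summary = QCSummary()
    prefix_len = len(key) + bc_len
    for read in reads:
        summary.tally("input")
        seq = read.seq
        if len(seq) < prefix_len + len(fwd) or not seq.startswith(key):
            summary.tally("failed_barcode")
            continue
        sample = norm_barcodes.get(seq[len(key) : prefix_len])
        if sample is None:
            summary.tally("failed_barcode")
            continue
        if iupac_mismatches(fwd, seq[prefix_len : prefix_len + len(fwd)]) != 0:
            summary.tally("failed_primer")
            summary._sample(sample)["failed_primer"] += 1
            summary._sample(sample)["input"] += 1
            continue
        payload = seq[prefix_len + len(fwd) :]
        if rev_oligo is not None:
            payload = trim_reverse_primer(payload, rev_oligo)
        if not payload:
            summary.tally("failed_primer")
            summary._sample(sample)["failed_primer"] += 1
            summary._sample(sample)["input"] += 1
            continue
        summary._sample(sample)["input"] += 1
        by_sample[sample].append(Read(read.id, payload, sample))
    return by_sample, summary


def qc_filter(
    reads: Iterable[Read], params: QCParams, summary: QCSummary | None = None
) -> tuple[list[Read], QCSummary]:
    """Apply homopolymer and length filters to demultiplexed, trimmed reads.

    When chained after demultiplex, pass its summary so reads are not
    double-counted; standalone, a fresh summary tallies inputs here.
    """
    standalone = summary is None
    if summary is None:
        summary = QCSummary()
    passed: list[Read] = []
    for read in reads:
        if standalone:
            summary.tally("input", read.sample)
        if max_homopolymer_run(read.seq) > params.max_homopolymer:
            summary.tally("failed_homopolymer", read.sample)
            continue
        if not params.min_length <= len(read.seq) <= params.max_length:
            summary.tally("failed_length", read.sample)
            continue
        summary.tally("passed", read.sample)
        passed.append(read)
    return passed, summary


def read_barcode_map(source) -> dict[str, str]:
    """Read a ``barcode<TAB>sample`` table."""
    close = isinstance(source, str)
    handle = open(source) if close else source
    try:
        out: dict[str, str] = {}
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            barcode, sample = line.split("\t")
            if barcode.upper() in out:
                raise QCError(f"duplicate barcode {barcode!r}")
            out[barcode.upper()] = sample
        if not out:
            raise QCError("empty barcode map")
        return out
    finally:
        if close:
            handle.close()
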