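"""In-silico primer evaluation against grouped reference sequences.

A fusion primer for 454 amplicon sequencing is adapter + key + barcode +
gene-specific oligo; only the oligo anneals to the template, so screening
slides the oligo (reverse primers as their reverse complement) across each
ungapped reference and records the minimum-mismatch window.  Degenerate
IUPAC codes in the oligo accept any base in their set; a degenerate code in
the *reference* counts as a match only when every base it could represent
is allowed by the oligo code (conservative subset rule).  Gaps never match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from itsclade.refdb import ReferenceDB

IUPAC_SETS: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement."""
    return seq.translate(_COMPLEMENT)[::-1]


class PrimerError(ValueError):
    pass


@dataclass(frozen=True)
class PrimerSpec:
    """One oligo with orientation and optional fusion parts.

    ``oligo`` is the gene-specific part (IUPAC codes allowed); adapter, key
    and barcode are sequencing-construct parts that never anneal and are
    excluded from specificity screening.
    """

    name: str
    oligo: str
    orientation: str  # "forward" | "reverse"
    adapter: str = ""
    key: str = ""
    barcode: str = ""

    def __post_init__(self) -> None:
        oligo = self.oligo.upper()
        if not oligo:
            raise PrimerError("empty oligo")
        bad = set(oligo) - set(IUPAC_SETS)
        if bad:
            raise PrimerError(f"non-IUPAC codes in oligo: {sorted(bad)}")
        if self.orientation not in ("forward", "reverse"):
            raise PrimerError(f"orientation must be forward/reverse, got {self.orientation!r}")
        object.__setattr__(self, "oligo", oligo)

    @property
    def fusion(self) -> str:
        """Full synthesised sequence: adapter + key + barcode + oligo."""
        return self.adapter + self.key + self.barcode + self.oligo

    @property
    def scan_sequence(self) -> str:
        """Oligo as it appears on the reference top strand."""
        if self.orientation == "reverse":
            return reverse_complement(self.oligo)
        return self.oligo


@dataclass(frozen=True)
class PrimerHit:
    ref_id: str
    mismatches: int
    position: int

    @property
    def perfect(self) -> bool:
        return self.mismatches == 0


@dataclass
class SpecificityReport:
    """Per-group aggregation of best-hit mismatch counts."""

    per_group: dict[str, dict]

    def perfect_fraction(self, group: str) -> float:
        return self.per_group[group]["perfect_fraction"]

    def min_mismatch(self, group: str) -> int:
        hist = self.per_group[group]["min_mismatch_histogram"]
        return min(k for k, v in hist.items() if v > 0)

    def to_rows(self) -> list[dict]:
        rows = []
        for group, stats in sorted(self.per_group.items()):
            hist = ",".join(
                f"{k}:{v}" for k, v in sorted(stats["min_mismatch_histogram"].items())
            )
            rows.append(
                {
                    "group": group,
                    "n": stats["n"],
                    "perfect_fraction": stats["perfect_fraction"],
                    "min_mismatch_histogram": hist,
                }
            )
        return rows


def iupac_mismatches(oligo: str, window: str) -> int:
    """Count oligo positions whose window base is outside the code's set.

    A gap or non-IUPAC character in the window never satisfies any code;
    a degenerate window base matches only if its set is a subset of the
    oligo code's set.
    """
    if len(oligo) != len(window):
        raise PrimerError(
            f"oligo length {len(oligo)} != window length {len(window)}"
        )
    mism = 0
    for oc, wc in zip(oligo.upper(), window.upper()):
        allowed = IUPAC_SETS.get(oc)
        if allowed is None:
            raise PrimerError(f"non-IUPAC code in oligo: {oc!r}")
        wset = IUPAC_SETS.get(wc)
        if wset is None or not wset <= allowed:
            mism += 1
    return mism


def best_hit(primer: PrimerSpec, ref_ungapped: str, ref_id: str = "") -> PrimerHit:
    """Minimum-mismatch window of the primer on an ungapped reference.

    Reverse primers are matched as their reverse complement on the given
    (top) strand.  Ties break to the smallest 0-based position.
    """
    probe = primer.scan_sequence
    ref = ref_ungapped.upper()
    if len(ref) < len(probe):
        raise PrimerError(
            f"reference ({len(ref)} nt) shorter than oligo ({len(probe)} nt)"
        )
    best_mism = len(probe) + 1
    best_pos = 0
    for pos in range(len(ref) - len(probe) + 1):
        m = iupac_mismatches(probe, ref[pos : pos + len(probe)])
        if m < best_mism:
            best_mism, best_pos = m, pos
            if m == 0:
                break
    return PrimerHit(ref_id=ref_id, mismatches=best_mism, position=best_pos)


def specificity_report(
    primer: PrimerSpec, db: ReferenceDB, group_rank: int
) -> SpecificityReport:
    """Best-hit mismatch distribution per taxonomy group at ``group_rank``."""
    if not 0 <= group_rank <= 3:
        raise PrimerError(f"group_rank must be in 0..3, got {group_rank}")
    if len(db) == 0:
        raise PrimerError("empty reference database")
    groups: dict[str, list[int]] = {}
    for rec in db.records:
        label = rec.taxonomy.ranks[group_rank]
        hit = best_hit(primer, rec.ungapped, rec.id)
        groups.setdefault(label, []).append(hit.mismatches)
    per_group: dict[str, dict] = {}
    for label, mms in groups.items():
        hist: dict[int, int] = {}
        for m in mms:
            hist[m] = hist.get(m, 0) + 1
        per_group[label] = {
            "n": len(mms),
            "perfect_fraction": hist.get(0, 0) / len(mms),
            "min_mismatch_histogram": hist,
        }
    return SpecificityReport(per_group)


@dataclass(frozen=True)
class Amplicon:
    """Predicted PCR product, inclusive of both primer sites."""

    start: int
    end: int
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start


def _qualifying_sites(probe: str, ref: str, max_mismatch: int) -> list[int]:
    return [
        pos
        for pos in range(len(ref) - len(probe) + 1)
        if iupac_mismatches(probe, ref[pos : pos + len(probe)]) <= max_mismatch
    ]


def in_silico_amplicon(
    fwd: PrimerSpec, rev: PrimerSpec, ref_ungapped: str, max_mismatch: int = 0
) -> Amplicon | None:
    """Predict the product of a forward/reverse primer pair on a template.

    The forward oligo must hit upstream of the reverse oligo's
    reverse-complement site, both within ``max_mismatch``.  The product runs
    from the outer edge of the forward site to the outer edge of the reverse
    site (primers included).  Returns None when no qualifying, correctly
    oriented site pair exists.  With multiple candidates the leftmost
    forward site and the nearest downstream reverse site are used.
    """
    ref = ref_ungapped.upper()
    fwd_probe = fwd.scan_sequence
    rev_probe = rev.scan_sequence
    if len(ref) < max(len(fwd_probe), len(rev_probe)):
        return None
    fwd_sites = _qualifying_sites(fwd_probe, ref, max_mismatch)
    rev_sites = _qualifying_sites(rev_probe, ref, max_mismatch)
    if not fwd_sites or not rev_sites:
        return None
    f = fwd_sites[0]
    downstream = [r for r in rev_sites if r >= f + len(fwd_probe)]
    if not downstream:
        return None
    r = downstream[0]
    end = r + len(rev_probe)
    return Amplicon(start=f, end=end, sequence=ref[f:end])
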