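"""Clade composition tables and within/between-clade distance summaries.

Composition tables have the layout of a field-survey report: one row per
clade, one column per sample, with per-sample percentages computed over the
reads assigned to the focal subcluster (SC5.1) only; reads assigned outside
it (e.g. *Prochlorococcus*) are tallied separately per sample.  Percentages
are rounded half-up to one decimal for presentation; counts are exact.

Distances are raw p-distances (proportion of differing positions, no
evolutionary correction), sharing the gap-run counting of the similarity
measure: a maximal run of gaps in one sequence is one difference and
both-gap columns are excluded from the denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd

from itsclade.align import CladeAssignment, similarity
from itsclade.refdb import ReferenceDB


class StatsError(ValueError):
    pass


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero (presentation rounding)."""
    factor = 10**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass
class CompositionTable:
    """Clade x sample counts with per-sample percentages over SC5.1 reads."""

    counts: pd.DataFrame  # clades x samples, int
    outgroup_counts: pd.Series  # per-sample reads outside the focal subcluster
    focal_subcluster: str = "SC5.1"

    @property
    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def percentages(self) -> pd.DataFrame:
        """Full-precision column percentages over focal-subcluster reads."""
        totals = self.sample_totals.astype(float)
        safe = totals.where(totals > 0, other=float("nan"))
        return (100.0 * self.counts.div(safe, axis=1)).fillna(0.0)

    def rounded_percentages(self, decimals: int = 1) -> pd.DataFrame:
        return self.percentages.map(lambda v: round_half_up(v, decimals))

    def to_long(self) -> pd.DataFrame:
        """Tidy long format: clade, sample, count, percentage."""
        pct = self.rounded_percentages()
        rows = []
        for clade in self.counts.index:
            for sample in self.counts.columns:
                rows.append(
                    {
                        "clade": clade,
                        "sample": sample,
                        "count": int(self.counts.at[clade, sample]),
                        "percentage": pct.at[clade, sample],
                    }
                )
        return pd.DataFrame(rows)

    def to_wide_text(self) -> str:
        """Counts row and percentage row per clade, tab-separated."""
        pct = self.rounded_percentages()
        lines = ["clade\tfield\t" + "\t".join(map(str, self.counts.columns))]
        for clade in self.counts.index:
            counts = "\t".join(str(int(v)) for v in self.counts.loc[clade])
            pcts = "\t".join(f"{v:g}" for v in pct.loc[clade])
            lines.append(f"{clade}\tcount\t{counts}")
            lines.append(f"{clade}\t%\t{pcts}")
        lines.append(
            "Sum\tcount\t" + "\t".join(str(int(v)) for v in self.sample_totals)
        )
        lines.append(
            "outgroup\tcount\t"
            + "\t".join(str(int(v)) for v in self.outgroup_counts)
        )
        return "\n".join(lines) + "\n"


def composition_table(
    assignments: Iterable[CladeAssignment],
    samples: Sequence[str],
    focal_subcluster: str = "SC5.1",
    clade_order: Sequence[str] | None = None,
) -> CompositionTable:
    """Aggregate clade assignments into a clade x sample composition table.

    Reads whose subcluster rank differs from ``focal_subcluster`` go to the
    per-sample outgroup tally and do not enter the percentages.  Assignment
    abundances (post-dereplication) are respected.
    """
    sample_list = list(samples)
    counts: dict[str, dict[str, int]] = {}
    outgroup = {s: 0 for s in sample_list}
    for a in assignments:
        if a.sample not in outgroup:
            raise StatsError(f"assignment for unknown sample {a.sample!r}")
        if a.taxonomy.subcluster == focal_subcluster:
            row = counts.setdefault(a.taxonomy.clade, {s: 0 for s in sample_list})
            row[a.sample] += a.abundance
        else:
            outgroup[a.sample] += a.abundance
    clades = (
        list(clade_order)
        if clade_order is not None
        else sorted(counts, key=_clade_sort_key)
    )
    df = pd.DataFrame(
        [[counts.get(c, {}).get(s, 0) for s in sample_list] for c in clades],
        index=pd.Index(clades, name="clade"),
        columns=sample_list,
        dtype=int,
    )
    return CompositionTable(
        counts=df,
        outgroup_counts=pd.Series(outgroup, name="outgroup"),
        focal_subcluster=focal_subcluster,
    )


_ROMAN = {
    "I": 1, "II": 2, "III": 3, "IV": 4, "V": 5, "VI": 6, "VII": 7,
    "VIII": 8, "IX": 9, "X": 10, "XI": 11, "XII": 12, "XIII": 13,
    "XIV": 14, "XV": 15, "XVI": 16, "XVII": 17, "XVIII": 18, "XIX": 19,
}


def _clade_sort_key(clade: str) -> tuple[int, int, str]:
    """Roman-numeral clades first in numeric order, then named clades."""
    if clade in _ROMAN:
        return (0, _ROMAN[clade], "")
    return (1, 0, clade)


# ---------------------------------------------------------------------------
# distances


def pairwise_distance(a: str, b: str, gap_mode: str = "run") -> float:
    """p-distance between two gapped sequences: 1 - similarity/100."""
    return 1.0 - similarity(a, b, gap_mode=gap_mode) / 100.0


@dataclass
class CladeDistanceMatrix:
    within: dict[str, float | None]  # None where < 2 members
    between: dict[tuple[str, str], float]
    n_pairs: dict[tuple[str, str], int] = field(default_factory=dict)

    def get_between(self, a: str, b: str) -> float:
        return self.between[(a, b) if (a, b) in self.between else (b, a)]

    def min_between(self) -> float:
        return min(self.between.values())

    def max_within(self) -> float:
        vals = [v for v in self.within.values() if v is not None]
        if not vals:
            raise StatsError("no clade has >= 2 members")
        return max(vals)

    def to_frame(self) -> pd.DataFrame:
        """Square matrix: within on the diagonal, between off-diagonal."""
        clades = sorted(self.within, key=_clade_sort_key)
        df = pd.DataFrame(index=clades, columns=clades, dtype=float)
        for c in clades:
            df.at[c, c] = float("nan") if self.within[c] is None else self.within[c]
        for (a, b), d in self.between.items():
            df.at[a, b] = d
            df.at[b, a] = d
        return df


def clade_distances(db: ReferenceDB, gap_mode: str = "run") -> CladeDistanceMatrix:
    """Mean pairwise within- and between-clade p-distances over a database."""
    if len(db) == 0:
        raise StatsError("empty reference database")
    groups: dict[str, list[str]] = {}
    for rec in db.records:
        groups.setdefault(rec.taxonomy.clade, []).append(rec.aligned_seq)
    if len(groups) < 2:
        raise StatsError("need at least 2 clades for between-clade distances")

    within: dict[str, float | None] = {}
    n_pairs: dict[tuple[str, str], int] = {}
    for clade, seqs in groups.items():
        if len(seqs) < 2:
            within[clade] = None
            continue
        dists = [pairwise_distance(x, y, gap_mode) for x, y in combinations(seqs, 2)]
        within[clade] = sum(dists) / len(dists)
        n_pairs[(clade, clade)] = len(dists)

    between: dict[tuple[str, str], float] = {}
    for ca, cb in combinations(sorted(groups, key=_clade_sort_key), 2):
        dists = [
            pairwise_distance(x, y, gap_mode)
            for x in groups[ca]
            for y in groups[cb]
        ]
        between[(ca, cb)] = sum(dists) / len(dists)
        n_pairs[(ca, cb)] = len(dists)
    return CladeDistanceMatrix(within=within, between=between, n_pairs=n_pairs)
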