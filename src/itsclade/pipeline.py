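"""End-to-end pipeline: demux -> QC -> align -> filter -> precluster -> classify.

Stage order is fixed and deterministic: demultiplex and quality-filter raw
reads; drop externally flagged chimeras; place reads into reference
coordinates; remove low-similarity (<90%) and short (incomplete-coverage)
reads; dereplicate and pre-cluster per sample (diffs <= 4); drop flagged
chimeras again post-clustering; assign clades by nearest neighbour (k=1);
tabulate clade composition.  An attrition table accounts for every read:
at each stage, input == surviving + sum(removed by reason).

Chimera detection itself is delegated to external tools; the pipeline
consumes a flag list of read ids and applies it at the two points where
the original protocol ran its two detectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from itsclade.align import (
    AlignedRead,
    CladeAssignment,
    FilterParams,
    KmerIndex,
    PreclusterParams,
    coverage_filter,
    dereplicate,
    knn_classify,
    place_read,
    precluster,
    similarity_filter,
)
from itsclade.readqc import QCParams, QCSummary, Read, demultiplex, qc_filter
from itsclade.refdb import ReferenceDB
from itsclade.stats import CompositionTable, composition_table
from itsclade.synth import FORWARD_OLIGO, KEY, REVERSE_OLIGO


class PipelineError(RuntimeError):
    pass


@dataclass
class AttritionTable:
    """Per-stage read accounting: input, removed-by-reason, surviving."""

    stages: list[dict] = field(default_factory=list)

    def add_stage(self, name: str, input_count: int, removed: dict[str, int]) -> int:
        surviving = input_count - sum(removed.values())
        if surviving < 0:
            raise PipelineError(
                f"stage {name!r} removes more reads than it received"
            )
        self.stages.append(
            {
                "stage": name,
                "input": input_count,
                "removed": dict(removed),
                "surviving": surviving,
            }
        )
        return surviving

    @property
    def survivors(self) -> int:
        if not self.stages:
            raise PipelineError("empty attrition table")
        return self.stages[-1]["surviving"]

    def check_conservation(self) -> bool:
        ok = all(
            s["input"] == s["surviving"] + sum(s["removed"].values())
            for s in self.stages
        )
        chained = all(
            self.stages[i + 1]["input"] == self.stages[i]["surviving"]
            for i in range(len(self.stages) - 1)
        )
        return ok and chained

    def assigned_percent(self, n_assigned: int) -> float:
        """Percent of surviving reads assigned (e.g. to the focal subcluster)."""
        if self.survivors == 0:
            raise PipelineError("no surviving reads")
        return 100.0 * n_assigned / self.survivors

    def to_rows(self) -> list[dict]:
        return [dict(s) for s in self.stages]


@dataclass
class PipelineResult:
    assignments: list[CladeAssignment]
    composition: CompositionTable
    attrition: AttritionTable
    qc_summary: QCSummary
    placements: dict[str, list[AlignedRead]]  # per-sample, post-filter

    @property
    def n_assigned_focal(self) -> int:
        focal = self.composition.focal_subcluster
        return sum(
            a.abundance
            for a in self.assignments
            if a.taxonomy.subcluster == focal
        )


def run_pipeline(
    reads: Iterable[Read],
    db_trimmed: ReferenceDB,
    barcodes: dict[str, str],
    key: str = KEY,
    fwd_oligo: str = FORWARD_OLIGO,
    rev_oligo: str | None = REVERSE_OLIGO,
    qc_params: QCParams = QCParams(),
    filter_params: FilterParams = FilterParams(),
    precluster_params: PreclusterParams = PreclusterParams(),
    chimera_flags: frozenset[str] | set[str] = frozenset(),
    samples: Sequence[str] | None = None,
    focal_subcluster: str = "SC5.1",
) -> PipelineResult:
    """Run the full analysis on multiplexed reads against a trimmed reference.

    ``db_trimmed`` must already be restricted to the classification region
    (see refdb.trim_to_region).  ``chimera_flags`` holds externally
    determined chimeric read ids, applied before placement and again after
    pre-clustering.  Two runs on identical inputs give identical output.
    """
    if len(db_trimmed) == 0:
        raise PipelineError("empty reference database")
    attrition = AttritionTable()
    reads = list(reads)

    # stage 1: demultiplex + QC
    by_sample, summary = demultiplex(reads, barcodes, key, fwd_oligo, rev_oligo)
    passed: dict[str, list[Read]] = {}
    for sample, sample_reads in by_sample.items():
        kept, summary = qc_filter(sample_reads, qc_params, summary)
        passed[sample] = kept
    attrition.add_stage(
        "demux_qc",
        summary.input,
        {
            "failed_barcode": summary.failed_barcode,
            "failed_primer": summary.failed_primer,
            "failed_homopolymer": summary.failed_homopolymer,
            "failed_length": summary.failed_length,
        },
    )

    # stage 2: chimera flags, first pass
    n_in = sum(len(v) for v in passed.values())
    n_chim = 0
    for sample in passed:
        kept = [r for r in passed[sample] if r.id not in chimera_flags]
        n_chim += len(passed[sample]) - len(kept)
        passed[sample] = kept
    attrition.add_stage("chimera_pass1", n_in, {"chimera": n_chim})

    # stage 3: placement + similarity/coverage filters
    index = KmerIndex(db_trimmed)
    placed: dict[str, list[AlignedRead]] = {}
    n_low = n_short = 0
    n_in = sum(len(v) for v in passed.values())
    for sample, sample_reads in passed.items():
        aligned = [place_read(r, db_trimmed, index) for r in sample_reads]
        kept, low = similarity_filter(aligned, filter_params)
        n_low += len(low)
        if filter_params.require_full_coverage:
            kept, short = coverage_filter(kept, db_trimmed.n_columns)
            n_short += len(short)
        placed[sample] = kept
    attrition.add_stage(
        "align_filter", n_in, {"low_similarity": n_low, "short": n_short}
    )

    # stage 4: dereplicate + precluster + chimera flags, second pass
    n_in = sum(len(v) for v in placed.values())
    n_chim2 = 0
    clustered: dict[str, list[AlignedRead]] = {}
    for sample, sample_reads in placed.items():
        clusters = precluster(dereplicate(sample_reads), precluster_params)
        kept = [c for c in clusters if c.read_id not in chimera_flags]
        n_chim2 += sum(c.abundance for c in clusters) - sum(
            c.abundance for c in kept
        )
        clustered[sample] = kept
    attrition.add_stage("precluster_chimera_pass2", n_in, {"chimera": n_chim2})

    # stage 5: nearest-neighbour classification
    assignments: list[CladeAssignment] = []
    for sample in clustered:
        for cluster in clustered[sample]:
            assignments.append(knn_classify(cluster, db_trimmed, k=1))

    sample_order = list(samples) if samples is not None else list(barcodes.values())
    comp = composition_table(assignments, sample_order, focal_subcluster)
    return PipelineResult(
        assignments=assignments,
        composition=comp,
        attrition=attrition,
        qc_summary=summary,
        placements=placed,
    )
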