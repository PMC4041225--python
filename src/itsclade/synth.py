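"""Synthetic clade-structured ITS fixtures with known truth.

The generator emulates the structure the pipeline exploits, not ITS
biology in detail: a random root sequence carries conserved blocks (the
forward-primer site, a tRNA-Ile block, and a tRNA-Ala block holding the
reverse primer's complement); clade ancestors diverge from the root and
members from their ancestor by uniform substitutions plus rare indels,
with the conserved blocks overwritten verbatim in every sequence.  Indels
are tracked into a gapped master alignment, so the output is a valid
uniform-width reference alignment with four-rank taxonomy and the region
between the forward primer and tRNA-Ile (tRNA excluded) as its RegionSpec.

Divergence parameters are *expected pairwise* proportions: members are
mutated at half the stated rate from their common ancestor.  Indels are
suppressed inside conserved blocks and in a 3-nt margin around block and
region boundaries, keeping boundary columns anchored (an alignment-
bookkeeping assumption, not a biological claim).

Reads are drawn from the in-silico amplicons of clade members per an
intended clade x sample composition, given 454-style errors
(substitutions, indels, homopolymer extension), and prefixed with
key + barcode + forward primer for demultiplexing.  Every emitted read is
recorded in a truth table (read id, sample, true clade, source member).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from itsclade.primers import PrimerSpec, in_silico_amplicon, reverse_complement
from itsclade.readqc import Read
from itsclade.refdb import ReferenceDB, ReferenceRecord, RegionSpec, TaxonomyPath

# the amplification system: picocyanobacterial forward primer (ITS-af) and
# the SC5.1-specific reverse primer (Syn-ar) sitting on the tRNA-Ala gene
FORWARD_OLIGO = "GGATCACCTCCTAACAGGGAG"
REVERSE_OLIGO = "AGGTTAGGAGACTCGAACTC"
KEY = "TCAG"

FORWARD_PRIMER = PrimerSpec("ITS-af", FORWARD_OLIGO, "forward", key=KEY)
REVERSE_PRIMER = PrimerSpec("Syn-ar", REVERSE_OLIGO, "reverse", key=KEY)

# default clade labels: the 18 SC5.1 clades resolvable from full-length ITS
DEFAULT_CLADES = (
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX",
    "XVI", "XVII", "CB1", "CRD1", "CRD2", "MS1", "MS2", "WPC1", "UC-A",
)

_BASES = "ACGT"
_INDEL_MARGIN = 3


class SynthError(ValueError):
    pass


def _random_seq(rng: np.random.Generator, length: int, max_run: int = 4) -> str:
    """Random sequence with homopolymer runs capped at ``max_run``.

    Genuine ITS templates carry no long homopolymers (the QC threshold of 6
    targets 454 over-calls, not template biology), so simulated roots must
    not either; the cap leaves headroom for mutations and sequencing errors
    to lengthen runs without striking error-free reads.
    """
    out: list[str] = []
    run = 0
    for _ in range(length):
        if run >= max_run:
            choices = [b for b in _BASES if b != out[-1]]
        else:
            choices = list(_BASES)
        base = str(rng.choice(choices))
        run = run + 1 if out and base == out[-1] else 1
        out.append(base)
    return "".join(out)


def _default_trna_ile(rng: np.random.Generator) -> str:
    # fixed-length conserved stand-in for the 74-nt tRNA-Ile gene
    return _random_seq(rng, 74)


@dataclass
class CladeModel:
    """Parameters of the clade-structured reference generator.

    Geometry defaults place the forward primer at position 30, a 180-nt
    informative spacer, the 74-nt tRNA-Ile block, a 55-nt second spacer and
    the 20-nt reverse-primer site, making the outer-edge amplicon 350 bp
    and the trimmed classification region 180 nt.
    """

    n_clades: int = 18
    members_per_clade: int | tuple[int, int] = 4
    root_length: int = 900
    between_divergence: float = 0.12
    within_divergence: float = 0.02
    indel_rate: float = 0.005
    conserved_blocks: list[tuple[int, str]] | None = None
    clade_names: tuple[str, ...] = DEFAULT_CLADES
    n_outgroup_clades: int = 0
    outgroup_rev_mismatches: int = 5
    seed: int = 0
    # geometry used when conserved_blocks is None
    fwd_pos: int = 30
    spacer1_len: int = 180
    spacer2_len: int = 55

    def __post_init__(self) -> None:
        if not 0 <= self.within_divergence < self.between_divergence:
            raise SynthError(
                "need 0 <= within_divergence < between_divergence"
            )
        if self.n_clades < 1:
            raise SynthError("n_clades must be >= 1")
        if self.n_clades > len(self.clade_names):
            raise SynthError(
                f"only {len(self.clade_names)} clade names available"
            )

    def resolved_blocks(self, rng: np.random.Generator) -> list[tuple[int, str]]:
        """(position, motif) conserved blocks; defaults derive the standard
        forward-primer / tRNA-Ile / tRNA-Ala(reverse-site) geometry."""
        if self.conserved_blocks is not None:
            blocks = sorted(self.conserved_blocks)
        else:
            ile_pos = self.fwd_pos + len(FORWARD_OLIGO) + self.spacer1_len
            ile = _default_trna_ile(rng)
            ala_pos = ile_pos + len(ile) + self.spacer2_len
            blocks = [
                (self.fwd_pos, FORWARD_OLIGO),
                (ile_pos, ile),
                (ala_pos, reverse_complement(REVERSE_OLIGO)),
            ]
        prev_end = 0
        for pos, motif in blocks:
            if pos < prev_end:
                raise SynthError(f"conserved blocks overlap at position {pos}")
            if pos + len(motif) > self.root_length:
                raise SynthError("conserved block extends past root_length")
            prev_end = pos + len(motif)
        return blocks


# ---------------------------------------------------------------------------
# sequence evolution with alignment bookkeeping
#
# a sequence is a list of per-root-position cells: cell[i] == '' means the
# root base is deleted; extra characters after the first are insertions
# attached downstream of position i


def _mutate(
    cells: list[str],
    sub_rate: float,
    indel_rate: float,
    rng: np.random.Generator,
    protected_sub: set[int],
    protected_indel: set[int],
    pools: list[list[int]],
) -> list[str]:
    out = list(cells)
    # substitutions are drawn as an exact count per pool (classification
    # region vs. flanks), so realized per-branch divergence equals the
    # stated rate in the region the distances are measured on, rather than
    # fluctuating binomially around it
    for pool in pools:
        eligible = [i for i in pool if out[i] and i not in protected_sub]
        n_sub = int(round(sub_rate * len(eligible)))
        if n_sub:
            for idx in rng.choice(len(eligible), size=n_sub, replace=False):
                pos = eligible[int(idx)]
                cell = out[pos]
                base = _BASES[(_BASES.index(cell[0]) + int(rng.integers(1, 4))) % 4]
                out[pos] = base + cell[1:]
    result: list[str] = []
    for i, cell in enumerate(out):
        if cell and indel_rate and i not in protected_indel and rng.random() < indel_rate:
            if rng.random() < 0.5:
                result.append(cell[1:])  # delete the root base, keep insertions
                continue
            cell = cell[0] + str(rng.choice(list(_BASES))) + cell[1:]
        result.append(cell)
    return result


def generate_reference(
    model: CladeModel,
) -> tuple[ReferenceDB, dict[str, str], RegionSpec]:
    """Simulate a clade-structured full-length reference alignment.

    Returns the ReferenceDB, a read-id-free truth map (sequence id -> true
    clade), and the RegionSpec spanning forward-primer end to tRNA-Ile end
    with the tRNA-Ile block excluded.  Deterministic given the model seed.
    """
    rng = np.random.default_rng(model.seed)
    blocks = model.resolved_blocks(rng)
    root = list(_random_seq(rng, model.root_length))
    protected_sub: set[int] = set()
    protected_indel: set[int] = set()
    for pos, motif in blocks:
        root[pos : pos + len(motif)] = list(motif)
        span = range(pos, pos + len(motif))
        protected_sub.update(span)
        protected_indel.update(span)
        protected_indel.update(range(max(0, pos - _INDEL_MARGIN), pos))
        protected_indel.update(
            range(pos + len(motif), min(model.root_length, pos + len(motif) + _INDEL_MARGIN))
        )
    # overwriting a block can merge a flank run with a block-edge run into a
    # homopolymer longer than real templates carry; re-draw the flank base at
    # each boundary so runs stay capped on both sides
    for pos, motif in blocks:
        for flank, inward, other in (
            (pos - 1, pos, pos - 2),
            (pos + len(motif), pos + len(motif) - 1, pos + len(motif) + 1),
        ):
            if 0 <= flank < model.root_length and flank not in protected_sub:
                if root[flank] == root[inward]:
                    forbidden = {root[inward]}
                    if 0 <= other < model.root_length:
                        forbidden.add(root[other])
                    root[flank] = str(
                        rng.choice([b for b in _BASES if b not in forbidden])
                    )
    from itsclade.readqc import max_homopolymer_run

    if max_homopolymer_run("".join(root)) > 6:
        raise SynthError(
            "conserved-block geometry leaves a homopolymer run longer than "
            "real templates carry; adjust block motifs or positions"
        )
    root_cells = list(root)

    # substitution pools: the informative classification region (between the
    # first two conserved blocks) and everything else
    all_positions = set(range(model.root_length)) - protected_sub
    if len(blocks) >= 2:
        region_positions = set(
            range(blocks[0][0] + len(blocks[0][1]), blocks[1][0])
        ) - protected_sub
        pools = [
            sorted(region_positions),
            sorted(all_positions - region_positions),
        ]
    else:
        pools = [sorted(all_positions)]

    def n_members() -> int:
        if isinstance(model.members_per_clade, int):
            return model.members_per_clade
        lo, hi = model.members_per_clade
        return int(rng.integers(lo, hi + 1))

    taxa: list[tuple[str, TaxonomyPath]] = []
    all_cells: list[list[str]] = []
    truth: dict[str, str] = {}

    def grow_clade(clade: str, taxonomy: TaxonomyPath, ancestor: list[str]) -> None:
        for j in range(n_members()):
            member = _mutate(
                ancestor,
                model.within_divergence / 2,
                model.indel_rate,
                rng,
                protected_sub,
                protected_indel,
                pools,
            )
            seq_id = f"{clade}_m{j:02d}"
            taxa.append((seq_id, taxonomy))
            all_cells.append(member)
            truth[seq_id] = clade

    for c in range(model.n_clades):
        clade = model.clade_names[c]
        ancestor = _mutate(
            root_cells,
            model.between_divergence / 2,
            model.indel_rate,
            rng,
            protected_sub,
            protected_indel,
            pools,
        )
        grow_clade(
            clade,
            TaxonomyPath(("Cyanobacteria", "Synechococcus", "SC5.1", clade)),
            ancestor,
        )

    # optional outgroups: Prochlorococcus-like, reverse-primer site degraded
    if model.n_outgroup_clades:
        _, ala_motif = blocks[-1]
        ala_pos = blocks[-1][0]
        for c in range(model.n_outgroup_clades):
            clade = f"OUT{c + 1}"
            ancestor = _mutate(
                root_cells,
                model.between_divergence,
                model.indel_rate,
                rng,
                protected_sub,
                protected_indel,
                pools,
            )
            degraded = list(ala_motif)
            sites = rng.choice(
                len(degraded), size=model.outgroup_rev_mismatches, replace=False
            )
            for s in sites:
                degraded[s] = _BASES[(_BASES.index(degraded[s]) + 2) % 4]
            for k, ch in enumerate("".join(degraded)):
                ancestor[ala_pos + k] = ch
            grow_clade(
                clade,
                TaxonomyPath(("Cyanobacteria", "Prochlorococcus", "HL", clade)),
                ancestor,
            )

    # master alignment: per root position, width = longest cell
    widths = [1] * model.root_length
    for cells in all_cells:
        for i, cell in enumerate(cells):
            widths[i] = max(widths[i], len(cell))
    col_of = [0] * (model.root_length + 1)
    for i in range(model.root_length):
        col_of[i + 1] = col_of[i] + widths[i]

    records = []
    for (seq_id, taxonomy), cells in zip(taxa, all_cells):
        aligned = "".join(cell.ljust(widths[i], "-") for i, cell in enumerate(cells))
        records.append(ReferenceRecord(seq_id, aligned, taxonomy))
    db = ReferenceDB(records, col_of[model.root_length])

    fwd_pos, fwd_motif = blocks[0]
    ile_pos, ile_motif = blocks[1]
    region = RegionSpec(
        start_col=col_of[fwd_pos + len(fwd_motif)],
        end_col=col_of[ile_pos + len(ile_motif)],
        excluded_blocks=((col_of[ile_pos], col_of[ile_pos + len(ile_motif)]),),
    )
    return db, truth, region


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class ReadModel:
    """Per-sample clade compositions and 454-style error rates.

    ``composition`` is a clade x sample matrix of intended read counts.
    ``read_length`` caps each read as the sequencer would; the default 250
    covers the forward primer, the informative spacer and part of the
    tRNA-Ile, like a GS-FLX read on a 350-bp amplicon.
    """

    composition: pd.DataFrame
    barcode_set: dict[str, str] = field(default_factory=dict)  # sample -> barcode
    sub_error: float = 0.0
    indel_error: float = 0.0
    homopolymer_extension_prob: float = 0.0
    read_length: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.sub_error, self.indel_error, self.homopolymer_extension_prob):
            if not 0 <= p < 1:
                raise SynthError("error rates must be in [0, 1)")
        if not self.barcode_set:
            rng = np.random.default_rng(self.seed + 7)
            self.barcode_set = {
                s: _random_seq(rng, 10) for s in self.composition.columns
            }
        if len(set(self.barcode_set.values())) != len(self.barcode_set):
            raise SynthError("duplicate barcode in barcode_set")


def _apply_errors(seq: str, model: ReadModel, rng: np.random.Generator) -> str:
    out: list[str] = []
    for ch in seq:
        if model.indel_error and rng.random() < model.indel_error:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(str(rng.choice(list(_BASES))))  # insertion before base
        if model.sub_error and rng.random() < model.sub_error:
            ch = _BASES[(_BASES.index(ch) + rng.integers(1, 4)) % 4]
        out.append(ch)
        if (
            model.homopolymer_extension_prob
            and len(out) >= 2
            and out[-1] == out[-2]
            and rng.random() < model.homopolymer_extension_prob
        ):
            out.append(ch)  # 454 homopolymer over-call
    return "".join(out)


def generate_reads(
    db: ReferenceDB,
    model: ReadModel,
    fwd: PrimerSpec = FORWARD_PRIMER,
    rev: PrimerSpec = REVERSE_PRIMER,
) -> tuple[list[Read], pd.DataFrame]:
    """Simulate multiplexed fusion reads with a truth table.

    Each intended read picks a uniformly random member of its clade,
    extracts the member's in-silico amplicon (primers included), applies
    errors, prefixes key + sample barcode, and truncates to read_length.
    Returns the reads and a truth DataFrame (read_id, sample, clade,
    member_id); every emitted read appears exactly once.
    """
    rng = np.random.default_rng(model.seed)
    by_clade: dict[str, list[ReferenceRecord]] = {}
    for rec in db.records:
        by_clade.setdefault(rec.taxonomy.clade, []).append(rec)

    amplicons: dict[str, str] = {}
    for rec in db.records:
        amp = in_silico_amplicon(fwd, rev, rec.ungapped, max_mismatch=0)
        if amp is not None:
            amplicons[rec.id] = amp.sequence

    reads: list[Read] = []
    truth_rows: list[dict] = []
    counter = 0
    for sample in model.composition.columns:
        barcode = model.barcode_set[sample]
        for clade in model.composition.index:
            n = int(model.composition.at[clade, sample])
            if n == 0:
                continue
            members = [r for r in by_clade.get(clade, []) if r.id in amplicons]
            if not members:
                raise SynthError(f"clade {clade!r} has no amplifiable member")
            for _ in range(n):
                rec = members[int(rng.integers(len(members)))]
                seq = _apply_errors(
                    KEY + barcode + amplicons[rec.id], model, rng
                )[: model.read_length]
                counter += 1
                read_id = f"read{counter:05d}"
                reads.append(Read(read_id, seq))
                truth_rows.append(
                    {
                        "read_id": read_id,
                        "sample": sample,
                        "clade": clade,
                        "member_id": rec.id,
                    }
                )
    return reads, pd.DataFrame(truth_rows)
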