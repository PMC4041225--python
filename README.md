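# itsclade

Clade-level classification of marine *Synechococcus* from 16S–23S rRNA
ITS amplicon reads.

Marine *Synechococcus* subcluster 5.1 (SC5.1) is subdivided into named
clades (I, II, III, IV, …, CRD1, WPC1, UC-A, …) with distinct ecological
niches, but the 16S rRNA gene is too conserved to tell them apart.  The
internal transcribed spacer (ITS) between the 16S and 23S genes is variable
enough for clade-level resolution, and a short (~180 nt) fragment of it —
the stretch between a picocyanobacterial forward primer and the conserved
tRNA-Ile gene — retains essentially all of the clade signal of the
full-length ITS.  `itsclade` implements the analysis pipeline built around
that observation, for amplicon surveys using an SC5.1-specific reverse
primer sitting on the tRNA-Ala gene:

1. **Primer screening** — IUPAC-aware in-silico evaluation of primers
   against a grouped reference set (perfect-match fractions, minimum-
   mismatch histograms, predicted amplicons).
2. **Reference construction** — a gapped full-length ITS alignment with
   four-rank taxonomy (`Cyanobacteria; genus; subcluster; clade`) trimmed
   to the classification region, deleting the uninformative tRNA-Ile block.
3. **Read QC** — demultiplexing on exact key+barcode and perfect forward
   primer, homopolymer cap (> 6 rejected), length window, read-through
   reverse-primer trimming.
4. **Placement** — template selection by shared 8-mers, then semi-global
   Needleman–Wunsch alignment (affine gaps, free terminal gaps) projecting
   each read into reference alignment columns; reads under 90% similarity
   to their best template, or not covering the full region, are removed.
5. **Pre-clustering** — greedy abundance-ranked merging of sequences within
   4 column differences, absorbing residual pyrosequencing errors.
6. **Classification** — k-nearest-neighbour with k = 1: each sequence takes
   the four-rank taxonomy of its single most similar reference.
7. **Reporting** — clade × sample composition tables (counts and per-sample
   percentages over SC5.1 reads), per-stage read-attrition accounting, and
   within/between-clade mean p-distance matrices.

A split-reference validation (`itsclade.validation`) and a synthetic-data
generator (`itsclade.synth`) make the whole pipeline testable end-to-end
with known truth and no external downloads.

## Worked example

Generate a synthetic survey and run the pipeline end to end:

```sh
itsclade synth ref --seed 7 --n-clades 6 \
    --out-alignment ref.fasta --out-taxonomy ref.tax --out-region region.yaml

itsclade simulate-split --alignment ref.fasta --taxonomy ref.tax \
    --region-start 51 --region-end 314 --exclude 240:314 --seed 3
```

(the region coordinates come from `region.yaml`; they vary with the seed).
The split-reference report prints one row per clade — held-out sequences,
how many classified back to their full-length clade, and the similarity
range to the nearest reference:

```
clade	n_full	n_short_agree	similarity_range
I	2	2	97.2-97.8
II	2	2	96.7-97.8
III	2	2	97.8-97.8
IV	2	2	97.8-97.8
V	2	2	97.2-97.2
VI	2	2	97.2-97.8
overall	12	12	agreement=1.000
```

`agreement=1.000` means the ~180-nt region classified every held-out
sequence identically to its full-length label; similarities above 90 mean
the similarity filter would not have discarded any of them.

The same in Python, with reads:

```python
import pandas as pd
from itsclade.synth import CladeModel, ReadModel, generate_reference, generate_reads
from itsclade.refdb import trim_to_region
from itsclade.pipeline import run_pipeline

db, truth, region = generate_reference(CladeModel(seed=42))
comp = pd.DataFrame({"A1": [30, 10], "P3": [5, 40]}, index=["I", "II"])
model = ReadModel(composition=comp, seed=3)
reads, truth_table = generate_reads(db, model)
result = run_pipeline(
    reads, trim_to_region(db, region),
    {b: s for s, b in model.barcode_set.items()}, samples=["A1", "P3"],
)
print(result.composition.counts)
```

```
       A1  P3
clade
I      30   5
II     10  40
```

The noiseless run returns the planted composition exactly; the attrition
table (`result.attrition.to_rows()`) shows zero removals at every stage.

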