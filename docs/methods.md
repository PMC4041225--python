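# Methods

## The classification problem

*Synechococcus* subcluster 5.1 clades are defined phylogenetically on
full-length 16S–23S ITS sequences (~900 alignment positions).  An amplicon
survey only sees a short fragment: the product of a picocyanobacterial
forward primer (`GGATCACCTCCTAACAGGGAG`) and an SC5.1-specific reverse
primer (`AGGTTAGGAGACTCGAACTC`, annealing on the tRNA-Ala gene), ~350 bp
outer edge to outer edge.  Classification uses only the region between the
forward primer and the tRNA-Ile gene, with the highly conserved tRNA block
deleted — roughly 180 informative nucleotides.  The package's premise,
checked by its validation module, is that this region separates clades:
mean between-clade p-distances stay above ~0.1 while within-clade
distances stay well below, so a nearest-neighbour rule with k = 1 suffices.

## Pipeline stages and their parameters

| stage | parameter | default | why |
|---|---|---|---|
| demultiplex | barcode/forward-primer match | exact | multiplexed 454 libraries; a single barcode error misassigns a sample, so only perfect prefixes are accepted |
| QC | max homopolymer run | 6 | the dominant 454 error mode is homopolymer over-call; genuine templates do not carry longer runs |
| QC | length window | 150–450 nt | stands in for the original flowgram-space filters; brackets the gel-excised 350–450 bp amplicon minus fusion parts |
| placement | template k-mer size | 8 | standard for ~180-nt fragments: specific enough to rank templates, short enough to tolerate errors |
| placement | scoring | +1/−1, gap −2 open, −1 extend, terminal gaps free | semi-global placement so a read nests in its template without penalty; a length-L gap run costs open + (L−1)·extend |
| filter | min similarity | 90% | reads *below* 90% to their best template are removed; 90.0 exactly is kept |
| filter | coverage | full region | reads with leading/trailing gap columns are removed to avoid length-driven misclassification |
| precluster | diffs | 4 | ≤ 4 column differences (~2% of the region) merges error variants into abundant parents while clades (> 10% apart) can never merge |
| classify | k | 1 | the nearest reference's four-rank taxonomy is taken verbatim; for k > 1 a majority vote applies, vote ties collapsing to the deepest common ancestor |

Chimera detection is delegated: the pipeline accepts a flag list of read
ids from any external detector and applies it twice (before placement,
after pre-clustering), mirroring the original two-pass protocol.

## Similarity and distance

Similarity between sequences in alignment columns skips columns gapped in
both, counts each maximal run of gaps in one sequence as a single
difference ("run" mode; a per-column mode is available), and is
100·matches/(matches+mismatches+gap runs).  Distances are raw p-distances,
1 − similarity/100, with no evolutionary correction — the quantities
reported are within/between-clade means over a reference set, where a
correction would shift all values monotonically without changing the
separation structure.  Percentages in composition tables are rounded
half-up to one decimal for presentation; counts are never rounded.

## Alignment algorithm

`needleman_align` is a three-state affine-gap dynamic program
(match/mismatch, gap-in-query, gap-in-reference) with free terminal gaps,
vectorised row-wise with numpy; the within-row gap state is resolved by
unrolling its recurrence into a running maximum.  Traceback ties resolve
diagonal-first, then gap-in-reference, so reruns are byte-identical.  The
implementation is verified in the test suite against a memoized
exhaustive recursion over all alignments and against independent rescoring
of the returned gapped strings.  Read insertions relative to the chosen
template cannot be represented in fixed reference coordinates and are
dropped with a per-read count — the same compromise any template-based
placement makes.

## Split-reference validation

Clade-labelled full-length sequences are partitioned (stratified per clade
by default, an unstratified mode exists; singleton clades go entirely to
the reference side, since a query whose clade has no reference left can
never agree).  The held-out half is trimmed to the classification region,
placed, and classified against the retained half; agreement compares the
assigned clade to the full-length-derived label.  On the default synthetic
fixture the expected outcome is 100% agreement with all similarities
above 90%, and agreement degrades monotonically as the between-clade
divergence is pushed down toward the within-clade level.

## Synthetic data: what it does and does not emulate

The generator produces a random root sequence carrying the conserved
blocks (forward-primer site, a 74-nt tRNA-Ile stand-in, the reverse-primer
complement) at positions giving a 350-bp amplicon and a 180-nt
classification region; clade ancestors and members diverge by uniform
substitutions (Jukes–Cantor-like, no rate heterogeneity) plus rare indels
tracked into a gapped master alignment.  Defaults: 18 clades (named after
the SC5.1 clades), 4 members each, 2% within-clade and 12% between-clade
divergence, indel rate 0.005/site.  Divergence parameters are *expected
pairwise* proportions (members mutate at half the stated rate from their
ancestor), and substitution counts are drawn exactly per compartment
(region vs. flanks) so realized divergence sits at the stated value
rather than fluctuating around it — the fixture's distance gap is a
construction, not a hope.

Two deliberate fidelity constraints: homopolymer runs in the simulated
root are capped at 4 (and runs merged at block boundaries are repaired),
because genuine ITS templates carry no long homopolymers — the QC
threshold of 6 exists for sequencer over-calls, and an uncapped random
root would make error-free reads fail QC for a reason real data never
exhibits; and indels are suppressed inside conserved blocks and in a 3-nt
margin around block/region boundaries so that region-boundary columns
stay anchored (otherwise a member deleting the first region column would
fail the full-coverage filter as an alignment-bookkeeping artifact).

Reads are drawn from members' in-silico amplicons per an intended
clade × sample composition, with optional substitution, indel and
454-style homopolymer-extension errors applied across the whole fusion
read (so barcode and primer errors exercise the QC bins), then truncated
to a read length (default 250 nt, covering the informative region and
part of the tRNA-Ile like a GS-FLX read).

Not emulated: flowgram-level noise, chimera formation, PCR bias,
phylogenetically realistic tree shapes, rate heterogeneity.  Passing tests
on these fixtures demonstrate the pipeline's logic — partitioning,
filtering, placement geometry, classification margins, accounting — not
performance on real flowgram data.

## Problem sizes

The default validation fixture is 72 sequences (18 clades × 4); end-to-end
runs use a few hundred reads over two samples.  These sizes exercise every
code path (all clades, both samples, every filter) while keeping the whole
suite and the acceptance script in the seconds-to-minutes range; the
underlying routines scale linearly in reads and references.

## Known limitations

- The tRNA-Ile boundaries are user-supplied alignment columns; no
  auto-detection is attempted (no reliable rule exists without a curated
  alignment).
- The 90%-similarity filter is applied against the placement template (the
  best shared-k-mer reference), not re-evaluated against the post-hoc
  nearest neighbour; on clean data the two coincide.
- Published field-survey figures that depend on the original GenBank/SRA
  material (database sizes, the 97% primer-match fraction on that set,
  per-station read counts) are not re-derivable from code; the package
  reproduces the computations and the printed-table arithmetic, not those
  data-bound numbers.
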