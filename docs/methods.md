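# Methods

This note documents the models, defaults and numerical choices behind
`edrec`, and what the synthetic-data tests do and do not establish
about real sequencing data.

## Reporter architecture and coordinates

Every designed oligo follows the layout

```
T7 promoter · forward handle · buffer · barcode · insert · RT handle
```

where the insert combines, depending on the library, an A-depleted
spacer, the 17-nt recorder (`TAGAATTACACCATAAT`, adenosines at 0-based
offsets 1, 3, 4, 7, 9, 12, 14, 15), and the 19-nt boxB stem loop
(`GGGCCCTGAAGAAGGGCCC`) in either orientation relative to the recorder.
Read 1 is modeled as the 79-nt window that starts at the barcode, so
every annotation coordinate (insert, recorder, flanks) is read-relative
and demultiplexing is an exact prefix match. Designs are in DNA sense;
analysis labels use RNA conventions (U), and the conversion is
presentation-only. Stem-loop positions are numbered 1–19 with the loop
at 8–12 and the closing pair at 7:13, matching conventional boxB
residue numbering; all machine-facing offsets are 0-based half-open.

## Barcodes

Reporter barcodes are 10-nt (20-nt for the DMS library) words over
{C, G, T}: excluding A means an A→G edit can never convert one valid
barcode into another. Pairwise Hamming distance ≥ 2 is guaranteed
constructively: a random prefix is extended with a modular checksum
symbol (all codewords sum to 0 mod 3), so any single substitution
breaks membership. This is exact, O(n), and deterministic given the
seed; the quadratic greedy-rejection sampler is retained for distances
above 2. A ternary length-ℓ distance-2 code holds at most 3^(ℓ−1)
words; requests beyond that raise an error naming the achievable
count.

## Library designs

* **Spacer-distance** — the 30-nt spacer is truncated in `step`-nt
  increments; each truncated spacer is split at every `step`-nt
  position into 5'/3' segments with the recorder inserted between, in
  both boxB orientations. The 3'-segment length is the recorder-to-boxB
  distance (0–30 nt at defaults).
* **Recorder-context** — the recorder's nine non-A positions are
  randomized in two groups enumerated over all four bases. With
  `group_size=5` the groups share the middle non-A position, giving
  2 × 4⁵ = 2,048 target sequences while tiling every non-A position.
  Designed adenosines are never altered, so the editing sites are
  pool-invariant. Randomized positions may become A; context analysis
  therefore merges flanking A/G into a purine class R (an edited A is
  indistinguishable from G).
* **Stem/loop randomization** — any 1-based window of the stem loop is
  fully enumerated (4^width variants); windows inside positions 8–12
  are labeled `loop_random`, others `stem_random`. The 4-nt stem
  window (3–6) gives the 256-variant stem library; the full loop
  window (8–12) gives 1,024 loop variants, 32 of which satisfy the
  GNRNA consensus (G8, purine 10, A12).
* **λN DMS** — every codon of the 22-codon ORF is replaced by all 64
  NNN codons (1,408 variants), each linked to a configurable number of
  20-nt A-depleted barcodes, with the ground-truth barcode→variant map
  emitted alongside. The printed wild-type nucleotide ORF is a
  synthetic reverse translation (common human codons) shipped as
  `LAMBDA_N_ORF_SYNTHETIC`; any coding sequence for the peptide works
  and real analyses should supply their own.

## Editing model of the simulator

The generator's job is ordinal fidelity — variants that bind better
must be edited more — not thermodynamic realism. Editing of each
designed adenosine is an independent Bernoulli draw with

```
p_site = background + time_scale · context_rate(5', 3') · occupancy
```

* `context_rate` is keyed by the designed flanking bases with purines
  merged ({U, C, R}²). Defaults follow the enzyme's measured bias:
  5'-U contexts are highest, UAU above all (0.35), UAR 0.175 and UAC
  0.116, while 5'-C contexts are lowest (0.012–0.02) and purine flanks
  intermediate.
* `occupancy` follows a binding isotherm c·K/(1 + c·K), implemented as
  a logistic of `score + log(concentration_scale)` where the linear
  score sums an intercept (−4), a GNRNA-loop bonus (+1.5), a U7 bonus
  (+1.0), a Watson-Crick 7:13 closing-pair bonus (+0.5), and
  0.15·(−ΔG). At the default concentration the wild-type hairpin sits
  near 72% occupancy and weak variants near 25%, giving the dynamic
  range the ranking analyses need; `concentration_scale ≫ 1` saturates
  every variant toward occupancy 1, which collapses GNRNA and stem
  stability enrichment — the expected non-specific regime at excess
  enzyme.
* `background` (0.005) is recruitment-independent editing;
  `seq_error_rate` applies per-base substitution errors to Read 1
  after editing. UMIs are uniform 7-mers, so collisions occur and
  deduplication is genuinely exercised.

Two generation routes exist: `simulate_reads` materializes FASTQ plus
a truth table, and `simulate_tallies` samples the same per-site model
directly into tally objects (all-distinct UMIs, no errors). The test
suite proves the read route is exactly inverted by the processor and
that both routes agree distributionally; large parameter-recovery runs
use the tally route for speed.

What the generator does **not** model: PCR jackpots beyond UMI reuse,
quality-score structure, realistic nanopore error profiles, secondary
structure occluding the recorder, or per-cell expression variability.
Passing recovery tests therefore demonstrates correctness of the
analysis under the stated sampling model, not robustness to every
artifact of real libraries.

## Read processing

Assignment, flank filtering and field extraction are exact string
operations at annotated coordinates (an optional Hamming-tolerant
rescue is deliberately absent from the default path). UMI
deduplication keeps the first occurrence per barcode in input order —
tallies are order-independent except through that documented
tie-break. An "edit" is a G call at a designed A offset; C/T calls are
tallied but count as non-edits, and the efficiency denominator is all
deduplicated reads. Conservation counters
(`reads_in = assigned + unassigned`, etc.) are emitted at every stage.

Long reads from the low-throughput assay are classified by presence of
the boxB motif `GCCCTGAAGAAGGGC`; A→G substitutions are counted in the
40 nt immediately 3' of the insertion site, and any read whose length
differs from its reference is discarded as an indel.

## Statistics

* **Bootstrap CIs** are parametric binomial: `iters` draws of size n
  at p̂, percentile 2.5/97.5 bounds. For a binary per-read outcome
  this matches label-resampling exactly in distribution; tests verify
  the endpoints against exact binomial quantiles.
* **Context profiles** are read-weighted means per context, so
  un-merged trinucleotide rows aggregate exactly into purine-merged
  rows. Context assignment uses designed flanking bases.
* **Group comparisons** use the two-sided Wilcoxon rank-sum test with
  tie correction (verified against exhaustive permutation for small
  n). Variant filters follow the assay's convention: strictly more
  than 200 UMIs, and optionally an exact U7·A13 closing pair.
* **Energy bins** sort ascending by ΔG (ties broken lexicographically
  by sequence) and slice into near-equal bins, earlier bins taking the
  extra variant (256 → 52/51/51/51/51). Bins containing only unfolded
  (ΔG = 0) variants have identical population means, so monotonicity
  across bins is checked one-sidedly at three standard errors rather
  than strictly.
* **DMS scores** pool reads across a variant's barcodes; the point
  estimate is the plug-in pooled fraction of ≥1-edit reads (the value
  the barcode-cluster bootstrap centers on, reported exactly so that
  identical groups score identically), with the bootstrap supplying
  the CI. Barcodes — the unit of biological replication — are
  resampled, not reads. The wild-type reference pools all variants
  translating to the intact peptide by default (`wt_definition=
  "synonymous"`); a codon-identical mode exists. Variants with fewer
  than 3 barcodes are flagged; stops are scored but excluded from
  per-residue means by default.

## Folding energies

The internal engine restricts structure space to a single hairpin: one
terminal loop (size ≥ 3) closed by one helix that may contain 1–2-nt
bulges and small internal loops. Watson-Crick stack free energies are
the standard published nearest-neighbor values at 37 °C; stacks
involving G·U wobbles use one representative value (−1.2 kcal/mol),
single-nucleotide bulges cost +3.8 with the flanking stack retained,
and hairpin initiation uses the standard size table with logarithmic
extrapolation. Positive totals are clamped to 0 (unfolded). This is
deliberately minimal — the libraries vary only a 19-nt stem loop — and
is validated by rank agreement (Spearman ≈ 0.85–0.9) against RNAfold,
which remains available as the `external` engine via subprocess.
Pseudoknots, multibranch structures and in-cell effects are out of
scope.

## Problem sizes and defaults

The shipped analyses run at desk scale: 256–2,048-variant libraries,
300–5,000 reads per variant, 20-seed replication for context recovery,
and 8 barcodes per DMS variant at 200 reads each (11,264 barcodes).
These sizes give binomial standard errors comfortably below the effect
sizes the ordinal checks assert, and the whole acceptance run completes
in seconds.

## Known limitations

* The context-rate table is a configuration default expressing a
  qualitative ordering, not a measured property of any enzyme batch.
* The internal ΔG engine is a ranking tool; absolute energies differ
  from full secondary-structure prediction by 1–3 kcal/mol on typical
  variants.
* Barcode demultiplexing is exact-match only by default; highly
  error-prone reads are dropped rather than rescued.
* The DMS wild-type definition ("synonymous") assumes synonymous codon
  replacements are functionally neutral at the peptide level.
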