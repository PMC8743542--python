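# Methods

This note documents the models and numerical choices behind each pipeline
stage, what the synthetic generator does and does not emulate, and the
known limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model and coordinates

All stages operate on `RepliconRecord`: an upper-cased A/C/G/T/N sequence
plus gene annotations in 0-based half-open coordinates. GenBank and GFF3
inputs (1-based inclusive) are shifted at the I/O boundary; BED output is
0-based half-open, GFF3 output 1-based inclusive. Gene symbols are
normalised to lowercase canonical tokens via suffix stripping
(`dnaA_1 → dnaa`) and a small editable product-text synonym table, because
public genomes are annotated inconsistently; tRNA-Ile is recognised from
`Ile` in a tRNA feature's product. N is legal in sequence but conservative
everywhere: it breaks TIR extension, scores −∞ in motif windows, and makes
an end unfoldable.

## Orientation

Canonical frame: *dnaN*/*dnaA* on '−', *parA*/*parB* on '+'. Each marker
present votes to keep or flip; majority decides and *dnaA* breaks ties
(oriC is anchored to *dnaA*, making its strand the least negotiable).
When a marker has several copies the copy nearest the replicon midpoint
votes — the origin region is central in these taxa, and telomere-proximal
paralogs (plasmid-style *parA*) would otherwise misorient the molecule.
Replicons with no marker at all are an error in strict mode and are passed
through unflipped (with the condition recorded) otherwise, since real
plasmids lacking *parAB* and *dnaA* exist. The flip is an involution and
re-deciding on an oriented replicon always answers "keep".

## TIR measurement

`perfect_tir` returns the largest `k ≤ ⌊L/2⌋` with
`prefix(k) == revcomp(suffix(k))` — computed as the first mismatch in a
vectorised base-wise comparison, and capped at `⌊L/2⌋` so the two halves
of a fully palindromic molecule never overlap. The imperfect TIR is an
**ungapped X-drop extension** of the same comparison: running score
(match +1, mismatch −2) is tracked until it falls more than 50 below its
maximum; the reported extent is the running-score maximum, and if identity
over that extent is below 90% the value falls back to the perfect length.
There is no published algorithm for "imperfect TIR" to follow; the X-drop
form was chosen because it is deterministic, oracle-checkable and has the
same qualitative behaviour as alignment-based end comparison. Gapped
extension is out of scope, so TIR pairs that diverge by indels are
reported at their ungapped extent only.

## Telomere classification

Ends are extracted in 3′-overhang presentation (right end verbatim, left
end reverse-complemented) so both read toward the terminus. Classification
is local alignment (match +1, mismatch −1, gap −2; Biopython
`PairwiseAligner`) of the 150-bp end against each panel reference and its
reverse complement. Identity is counted over aligned columns (gaps count
against it); coverage is the aligned span of the **reference** as a
percent of its length — the coverage-over-reference reading was chosen
because a short physical telomere fragment should still be assignable from
a partial hit; the thresholds (identity ≥ 76%, coverage ≥ 19%) are applied
uniformly to all six classes and are overridable. Among passing classes
the highest raw alignment score wins; runners-up are kept for diagnostics.

The shipped panel is a **synthetic stand-in** (one fold-competent,
tri-loop-rich 150-mer per class, labelled `synthetic` in the FASTA).
Its composition was calibrated once, before the test suite existed, to the
documented behaviour of the thresholds: at ~40–47% GC the measured
false-assignment rate of random 72%-GC 150-mers is ~0.3% and cross-class
assignments do not occur, while planted ends survive 10% point mutation.
Telomeric ends being markedly AT-richer than the genomes they cap is also
the biologically expected regime. Conclusions about *real* telomere
classes require substituting real reference ends via `--panel`.

## Stem-loop folding

The folding engine finds the minimum-free-energy **nested** structure with
pairs at most `dmax = 20` nt apart and hairpins of ≥ 3 unpaired nt —
the locality constraint used for telomere folding, which also makes the
algorithm exact and fast: every loop closed by a pair lives inside a
≤ 21-nt window, so the dynamic programme tracks the exact number of
unpaired bases per loop and applies the Jacobson–Stockmeyer penalty
`A + B·ln(n)` (defaults A = 10 kJ/mol, B = 4.41 kJ/mol ≈ 1.75·R·T at
30 °C) to hairpin, bulge, interior and multibranch loops alike, without
the linear multiloop approximation usual in Zuker-style folders. Adjacent
pairs score nearest-neighbor stack energies from an editable data file
(SantaLucia unified ΔG°37 values converted to kJ/mol). Exterior unpaired
bases are free. Ties break toward fewer pairs, then the lexicographically
earliest pair set. Temperature and salt are carried as metadata only — the
stack table is not rescaled, so reported ΔG values are comparable within a
configuration but are **not** literature free energies, and no attempt is
made to reproduce published Mfold values.

G·T wobble pairing is available (`allow_wobble=True`) but **off by
default**: a G·T pair has no image under reverse complementation (it maps
to A·C), so wobble folding is not strand-symmetric, and the pipeline's
symmetry contract — ΔG invariant under reverse complement — takes
precedence. The wobble stack is a single flat value in the data file, not
a per-context table.

An independent cross-check scores explicit pair sets by loop decomposition
(`score_structure`) and is used by the tests to compare the DP against
exhaustive enumeration for short sequences.

## parS scanning

Weight matrices use background-proportional pseudocounts:
`W(b,i) = log2(((counts(b,i) + k·p(b)) / (N + k)) / p(b))`, `k = 1` by
default. The default background is the scanned replicon's own
mononucleotide composition (~72% GC in this clade) — the defensible choice
for high-GC genomes, and one that materially affects hit counts; uniform
background is a flag away. Scanning slides the matrix over both strands in
a vectorised pass; hits must exceed the threshold **strictly** (> 15), and
a window passing on both strands (the motif is quasi-palindromic) is
reported once on the higher-scoring strand, '+' on ties, with a 1e-9
tolerance absorbing summation-order noise between the forward and the
rearranged reverse-strand pass.

The shipped count table is a **synthetic stand-in** for a 1030-site parS
alignment, built around the quasi-palindromic 16-bp bacterial consensus
TGTTTCACGTGAAACA with self-reverse-complement-symmetric counts. Its
sharpness was set by exact convolution of the per-position score
distributions: sites sampled from the matrix score > 15 with probability
≈ 1 − 10⁻⁴, while a 72%-GC background window passes with probability
≈ 2·10⁻⁹ (≈ 0.04 expected spurious hits per 9 Mb genome, both strands).
Real-genome hit counts depend on the real matrix and background
configuration and are not claimed here.

## oriC, origin island, statistics

oriC is operationalised as the **last transcribed base of dnaA** on the
oriented replicon — the left-most genomic coordinate of the CDS, since
dnaA runs right-to-left after orientation. The island is anchored on gene
features, not whole-genome alignment: start of the nearest tRNA-Ile left
of oriC and end of the nearest *dnaB* right of it, each within a 200 kb
search window (missing or inverted anchors are errors naming the anchor).
Island location is reported as the midpoint percent of replicon length by
default (start-based reporting via flag) — the reference point had to be
fixed by choice. parS sites split left/right at oriC with
`start ≤ oriC → left` (a site exactly at oriC is left; configurable
convention), island membership is `start ∈ [island_start, island_end)`,
and mean gaps are successive-start differences within a compartment,
defined only when a compartment holds ≥ 2 sites. Cohort summaries are
arithmetic means and min–max ranges, chromosomes (≥ 1 Mb by default) and
plasmids aggregated separately, metrics missing on a replicon excluded
rather than zero-filled.

## Synthetic genomes

The generator emulates: i.i.d. mononucleotide background at configurable
GC (default 0.72); class-specific 150-bp telomeres planted verbatim at the
ends (left end reverse-complemented); a TIR block copied to both ends with
the copy mutated at a configurable rate beyond the perfect core — the
first base past the core is always mutated, so the planted perfect length
is exact by construction; the island gene cassette (tRNA-Ile, gyrB, gyrA,
recF, dnaN, dnaA, parA, parB, ssbA, dnaB on canonical strands) placed
deterministically inside the island with dnaA's last base defining planted
oriC; and parS sites sampled from the weight matrix (or consensus-only),
placed by rejection sampling outside genes/TIRs. Fractions (right bias
0.8, island fraction 0.45) are realised as **exact rounded counts**, not
Bernoulli draws, so a genome's planted composition matches its
configuration to rounding and recovery checks are not confounded by
sampling noise in the truth itself; realised counts are recorded in the
truth table. Identical (config, seed) yields byte-identical FASTA, GFF3
and truth JSON.

Cohort defaults are the study conditions: length uniform on
[6,841,649, 10,851,423] (mean 8,846,536), island size uniform on
[48,019, 54,091] (mean 51,055) at a midpoint fraction U(0.4125, 0.5325),
perfect TIR uniform on [150, 75,830] (mean 37,990) with an imperfect
extension averaging 39,102 bp at 5% divergence, and 11–35 parS sites per
genome (mean 23). Telomere classes are drawn per genome (archetypal most
frequent) with both ends sharing a class — a nonzero TIR logically forces
the two ends to carry the same terminal sequence, so mixed-class replicons
are generated only with zero-length TIRs.

What the generator does **not** emulate: codon structure or realistic
coding sequence (annotations are coordinate-only), k-mer composition,
rRNA operons, genome rearrangements between cohort members, replichore
length asymmetry, or parS clustering gradients within an arm (bulk sites
are uniform in their compartment). Passing recovery tests therefore
demonstrates the measurement machinery, not robustness to every
complication of real genomes — notably annotation errors, which are the
dominant failure mode in practice.

## Problem sizes in the standard runs

The shipped test suite folds ≤ 25-nt sequences against full structure
enumeration (500 draws), checks the TIR measurer against a base-wise
oracle on 1,000 instances up to 10 kb, the scanner against a per-window
scorer on 200 instances up to 50 kb, and runs the full 20-genome
cohort at natural chromosome sizes (6.8–10.8 Mb). The acceptance script
repeats the cohort run and smaller oracle sweeps; both finish in a few
minutes on a single CPU.

## Known limitations

- Imperfect TIRs are ungapped; indel-diverged TIRs are under-measured.
- Telomere and parS reference data are synthetic stand-ins (see above);
  real-data conclusions require real panels.
- The folding model is a reduced nearest-neighbor + logarithmic-loop
  model: structures and energy rankings are meaningful, absolute ΔG is not
  calibrated, and suboptimal ensembles are not enumerated.
- Orientation, oriC and island delineation trust the gene annotation;
  there is no sequence-based fallback (GC skew is deliberately out of
  scope).
- One island per replicon is assumed; with several tRNA-Ile copies near
  oriC the nearest is taken.
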