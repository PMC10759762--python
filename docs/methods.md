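# Methods

## Karyotype statistics

A chromosome is classified from its arm ratio r = long/short (arms
normalized so short ≤ long): `T` when the short arm is absent, `t` when
r > 7.00, `st` for 3.01 ≤ r ≤ 7.00, `m` for 1.01 ≤ r ≤ 1.70 and `M` at
r ≈ 1 (≤ 1.005, absorbing rounding). The 1.71–3.00 interval is classified
`sm` with a warning so the classifier is total, although the focal taxa do
not use it. Boundary inclusivity follows the printed ranges: `t` is
strictly above 7.00; `st` includes both 3.01 and 7.00.

Replicate metaphase cells are aggregated by ordering each cell's
complement by (type class, descending total length) and averaging arm
lengths position-wise across cells. TCL is the mean over cells of half the
summed complement length (the haploid total); L/S is the mean over cells
of longest/shortest; relative lengths are percentages of the haploid total
of the averaged complement. Under this aggregation the per-cell and
averaged-complement definitions of TCL coincide.

Asymmetry indices follow the Romero Zarco definitions: A1 = 1 − (Σ
b_i/B_i)/n over the n homolog pairs (mean short arm b, mean long arm B per
pair; b/B = 0 for telocentric pairs) and A2 = s/x̄ over all 2n chromosome
lengths, with the sample standard deviation (ddof = 1). Homologs are
paired within each type class by descending length; in strict mode an odd
within-type count is an error, while the default lenient mode keeps the
leftover chromosome as a singleton group contributing its own b/B — this
is how structurally heterozygous hybrid complements (5t, 3T) are handled,
and it is documented rather than hidden because per-chromosome variants of
A1 exist in the literature and would change digits.

The Stebbins type combines a digit from the proportion p of chromosomes
with arm ratio > 2.00 (p = 0 → 1; p ≤ 0.5 → 2; p < 1 → 3; p = 1 → 4) with
a letter from L/S (< 2 → A; 2–4 → B; > 4 → C). When only a formula is
available, st/t/T count as ratio > 2 and M/m as ≤ 2; the ambiguous sm band
is counted as > 2 (its midpoint exceeds 2). The letter boundaries are
closed on B, consistent with published complements at L/S 2.45 (B) and
4.31 (C).

## Additivity model

Only balanced (euploid) gametes are modeled: every per-type count must be
even and is halved exactly. Aneuploid or unreduced gametes are out of
scope and raise a dedicated error. Type classes match at full resolution
(m ≠ sm). Karyotype additivity is orientation-blind; the cross is oriented
by the plastome evidence. Parent-pair screening evaluates all unordered
pairs, self-pairs included, so a "hybrid" identical to a panel member is
reported as a possible self-pair rather than silently excluded.

## Phenetics

"Average Euclidean distance" is implemented as the root-mean-square
difference over variables (d = plain Euclidean / √p), the convention of
the INFOSTAT-style packages used for morphometric work; plain Euclidean is
available behind a flag because published dissimilarity ranges cannot
disambiguate the scaling. Variables are z-scored with ddof = 1; constant
columns carry no information and are zeroed with a warning. UPGMA is
scipy's unweighted average linkage; node heights are half the merge
distance and Newick branch lengths are parent height − child height at six
decimals. Flower colours enter as user-supplied numeric encodings; the
package makes no claim to reproduce any particular colour-chart encoding,
which is why published dissimilarity magnitudes are not a target.

## Plastome structure

Inverted repeats are required to be exact: detection seeds k-mer matches
(k = 25) between the sequence and its reverse complement, groups seeds by
anti-diagonal, extends each candidate outward base-by-base, and keeps the
longest pair of disjoint reverse-complementary copies on the circle. The
sequence is rotated so the longer single-copy region (LSC) starts at
position 1; the IR copy immediately after the LSC is IRb. Without
annotations the strand is canonicalized by choosing the lexicographically
smaller of the two LSC-first orientations, so a genome and its reverse
complement give identical output. Coordinates are 1-based closed
throughout (GenBank convention).

A gene "spans" a junction when it has ≥ 1 bp on both sides; a gene ending
exactly at a junction is reported as overlapping with zero bases on the
far side, not as a nearest gene. When nothing overlaps, the nearest gene
on each side within a 1000 bp window is reported with its distance in
bases from the junction. GC content excludes Ns from the denominator.

## Variant calling

Sequences are compared collinearly (both rotated to the LSC-start
convention first when they are full plastomes): 31-mers unique in both
sequences and shared between them are chained by longest strictly
increasing subsequence, merged into same-diagonal blocks, and the
unanchored segments in between are aligned globally (match +1, mismatch
−1, gap open −4, gap extend −1; N scores 0 against everything and never
seeds an anchor). Alignment columns become substitution, insertion
(left-anchored, empty reference span) and deletion (empty alternate)
calls; indels are left-aligned against the full reference so shared-site
counting is well defined. Variants closer than ~2k bp may share one gap
segment; they are still called individually, but planted-truth guarantees
in the simulator keep edits ≥ 100 bp apart so the expected call set is
unambiguous. Shared SNP sites are substitutions identical in (position,
reference allele, alternate allele); the maternal ranking uses this count
with the symmetric difference of full call sets as tie-break, and its
margin (top minus runner-up) gates confidence. Confidence is a boolean,
not a probability — no statistical model is imposed on it.

## SSR scanning

Per unit size u ∈ 1..6 the scanner walks left to right, extends a
primitive (aperiodic) motif to its maximal full-repeat count, reports the
run when it meets the unit's threshold and resumes after it. Default
thresholds are 10, 5, 4, 3, 3, 3 repeats for unit sizes 1–6 — chosen so
the canonical published loci, a 10-repeat mononucleotide and a 3-repeat
pentanucleotide, are admitted — and are fully configurable because MISA
settings vary between studies. Motifs are reported as observed, not
cycle-canonicalized. Loci separated by at most 100 interruption bases
merge into compound loci (negative gap disables merging). Catalogue
diffing matches loci by motif within a ±20 bp start tolerance (upstream
indels shift coordinates), classifying matches as identical or
repeat-count-changed, then pairs leftover same-size same-count loci at the
same site as motif-changed, and reports the rest as private.

## Synthetic data

Karyotype simulation draws one arm-ratio target per homolog pair uniformly
from per-type ranges and multiplies each arm by exp(N(0, cv)) per cell
(log-normal, cv defaults to 0.05 over 5 cells). The target ranges — m:
1.05–1.50, sm: 1.85–2.85, st: 3.50–6.00, t: 8–12, T: short arm 0 — sit
inside the classification bands with a deliberate noise margin: the
cell-averaged ratio has σ ≈ √2·cv/√n_cells ≈ 0.032 relative, so a target
at 1.65 would cross the m/sm boundary at 1.70 far too often, while 1.50
keeps the crossing probability negligible and classification recovery at
100% across seeds. Pair total lengths are linearly spaced to hit a target
TCL and L/S; the presets reproduce the two parental karyotypes at study
scale (22 = 10t + 12st, TCL 115.61 µm, L/S 1.73; 14 = 8m + 6T, TCL 145.95
µm, L/S 2.45). F1 simulation takes one homolog per parental pair
(homologs share targets, so the gamete is exactly balanced) and re-noises
measurements.

Plastome simulation concatenates random LSC | IRb | SSC | revcomp(IRb)
(defaults 3000/1000/800/1000 bp — a reduced-scale architecture that keeps
the full pipeline in milliseconds; real plastomes are ~158 kb and a larger
spec can be passed for stress tests). The first and last base of each
single-copy region are fixed non-complementary so the planted IR is
exactly maximal and detection recovers it bit-for-bit. Gene stubs straddle
the junctions with the canonical plastid layout (rps19 176 bp LSC / 34 bp
IRb; ndhF 107 bp duplicated in the IRb; ycf1 41 bp into the IRa; an IRa
rps19 fragment 3 bp from, and psbA 86 bp beyond, the IRa-LSC junction).
Planted SSRs are written with repeat-breaking flank bases and placed
farther apart than the compound-merge gap.

Offspring derivation applies n substitutions and short (1–3 bp) indels at
positions ≥ 100 bp apart (and away from a parent's own edit sites in trio
simulation); planted indels are pre-left-aligned so the edit log is the
exact expected output of variant calling. The trio generator derives two
parents independently from one ancestor (8 substitutions + 2 indels each
by default) and the hybrid from the chosen maternal parent (3 + 1 private
edits), giving a shared-site margin of ~8 — comfortably above the
discriminability condition that parental divergence exceed the private
mutation count. The trait-table generator produces parents at study-like
values and hybrids as maternally biased intermediates (weight 0.75 toward
the seed parent, small Gaussian noise), which is what makes the four-taxon
UPGMA pair each hybrid with its maternal parent.

What the generators do **not** emulate: aneuploidy and unreduced gametes,
IR copies differing between taxa, paternal plastome leakage or
heteroplasmy, rearrangements or large indels, sequencing error, and any
real flower-colour encoding. Passing tests therefore demonstrate the
pipeline's correctness on data obeying the model's assumptions, not
robustness to violations of them.

## Problem sizes and determinism

Test and acceptance runs use the reduced plastome scale (~5.8 kb), 100
seeds for IR-partition and SSR-oracle checks, 50 seeds for planted-variant
recovery and 50 seeds × 2 reciprocal directions for full trio recovery —
sizes chosen to exercise the statistical claims while keeping the whole
suite under a minute. Every generator is deterministic given its seed;
re-running the pipeline on identical inputs produces byte-identical JSON.

## Known limitations

* A1 on odd-count (hybrid) complements depends on the lenient singleton
  convention described above.
* Exact-repeat IR detection will report a truncated IR when the two copies
  differ by even one base; a mismatch-tolerant extension is not
  implemented because the focal genomes have identical IR copies.
* The anchor caller assumes near-identity; divergence high enough to
  exhaust shared unique 31-mers raises an insufficient-homology error
  rather than degrading silently.
* "Missing" variant counts are deletions relative to the reference with no
  length cap.
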