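# Methods

This note documents the models and procedures behind `guardamp`, the
defaults and why they were chosen, what the synthetic generators emulate,
and the limits of what a passing test establishes.

## CDS extraction

**ORF model.** An ORF is a maximal stop-free codon run in one of the six
reading frames, ending at a stop codon or at the transcript end; the stop
codon is excluded from the reported length and protein. Runs truncated by
the transcript end are kept, because assembled transcripts are frequently
fragmentary and a truncated CDS is still recoverable by homology. The
175-nt minimum is applied to the stop-free run itself. Codons containing N
translate to X and never count as stops. The homology route does not
require a Met start (fragments lack one); the signal-peptide route does,
per its biology. A `require_met` flag restricts the homology route as well
for users who prefer the stricter convention. Coordinates are 0-based,
half-open, stored on the forward strand with a strand flag, so records
compose directly with slicing and with standard interval tooling.

**Homology search.** Smith–Waterman local alignment with BLOSUM62 and
affine gaps (open 11, extend 1) — the classic protein-search
parameterization — preceded by a shared 4-mer prescreen for speed. This is
a deliberate desk-scale stand-in for a database BLAST: exact, reproducible
and dependency-free, at the cost of speed on large references. "Coverage"
is coverage of the *matched* (subject) protein: the extraction rule asks
whether the ORF accounts for enough of a known protein, not the reverse.
Query-side coverage can be derived from the reported alignment spans.

**Signal-peptide heuristic.** The score is a weighted sum of three classic
signal-peptide features computed on the first 30 residues:

* net positive charge of the n-region (residues 1–5), weight 0.25;
* the best 8-residue Kyte–Doolittle window in residues 6–20 (h-region),
  weight 0.45;
* a small-residue (A/G/S/C) match at the −3/−1 positions of a candidate
  cleavage site scanned over residues 15–30, weight 0.30.

Each component is clipped to [0, 1]; the default decision threshold is
0.8, calibrated on the synthetic generator where it achieves sensitivity
1.0 on planted signal peptides and specificity ≈ 0.98 on decoy ORFs. The
heuristic is a documented, transparent gate — it is *not* a trained
predictor, and on real sequences it should be treated as a coarse filter
whose threshold the user may retune. The pipeline contract is the boolean
call; the score exists for inspection and calibration.

**Consolidation.** Greedy longest-first clustering: each sequence joins the
first existing representative to which its global-alignment identity
(matches / alignment length, terminal gaps included) is ≥ 0.95, else founds
a new cluster. Ties in length break lexicographically by id, making the
outcome deterministic. A length-ratio prescreen skips pairs that cannot
reach the threshold. This reproduces the redundancy-removal role of
CD-HIT-style tools without their word-index heuristics; at desk scale the
exact computation is affordable and easier to reason about.

**TPM and the expression filter.** TPM divides each count by the CDS
effective length, then normalizes each library to one million; columns sum
to 1e6 by construction (an all-zero library yields an all-zero column with
a warning rather than an error, since dropping a library is a QC decision).
The retention rule — mean TPM ≥ 5 in at least one biological condition — is
a mean over replicates, deliberately: a transcript strongly expressed in
one replicate of one condition can pass, which matches how expression
filters are applied to replicated designs.

## Differential expression

The engine is an exact-style negative-binomial test, a transparent
stand-in for the mainstream exact-test DE packages; it is validated by
calibration and parameter-recovery properties, never by numeric equality
with any specific package (whose normalization and dispersion machinery
differ in detail).

1. **Normalization**: median-of-ratios size factors against the
   geometric-mean reference, computed on genes observed in all libraries.
2. **Dispersion**: a single common φ in var = μ + φμ², estimated by
   method of moments — per gene and group, (s² − m) and m² are pooled, and
   the pooled ratio is computed *within expression deciles*, taking the
   median across deciles, floored at 1e-4. The decile-median construction
   matters: a single global ratio is dominated by the handful of most
   abundant genes, and with n = 3 replicates that made the test's type-I
   error drift several points across simulation seeds; binning restores a
   stable estimate (empirical α 0.040–0.052 at nominal 0.05 across seeds).
3. **Test**: counts are scaled to the common size and rounded; group sums
   of n i.i.d. NB(μ, φ) variables are NB(nμ, φ/n), and conditioning on the
   total gives an exact two-sided p-value by enumerating all splits no more
   likely than the observed one. Genes with zero counts in both groups get
   p = 1 and log2FC = 0.
4. **Effect size**: log2 of the ratio of normalized group means with a 0.5
   pseudo-count per mean, so zeros are finite and group swap exactly
   negates the estimate.
5. **Calling**: modulated iff |log2FC| > 1 *and* BH-FDR < 0.05, both
   boundaries strict.

**Mapping-rate QC.** A library is excluded when its rate falls below the
median of the *other* libraries minus k × (1.4826 × MAD), k = 5 by default.
Leave-one-out keeps a gross outlier from inflating its own baseline; the
MAD-based SD makes the envelope robust; k = 5 separates a failed library
(≈ 9% against a 29% ± 1% consensus) from ordinary scatter by a wide margin.
k is configurable.

**Proteomics filter.** Proteins flagged as contaminants or host, and
proteins detected in fewer than 2 of 3 replicates, are dropped. Intensities
are handled on the log2 scale throughout.

## AMP signatures

**Defensin.** Mature peptide of 30–60 residues with exactly six cysteines
whose five consecutive gaps fall in windows derived from the two
characterized midgut defensins (common gap pattern 7, 4, 10, 8, 2) ± 3
residues. Connectivity is assigned canonically (C1–C4, C2–C5, C3–C6);
subtypes are `CVMK_terminal` (C-terminal CVMK motif) and
`Tyr_adjacent_terminal_Cys` (tyrosine immediately after the last cysteine).
The scanner reports the cysteine positions it observes and derives the
bridge pairs from them, rather than trusting externally supplied bridge
numberings, which are prone to off-by-one indexing errors.

**Microplusin/ricinusin.** ≥ 60 residues, overall His fraction ≥ 0.12 and a
six-cysteine pattern; type 2 when the C-terminal 25 residues have a His
fraction ≥ 0.25 (the His-rich tail that distinguishes
microplusin/hebraein-like peptides from type 1 ricinusins).

**GILT.** ≥ 100 residues with both a CXXC active site and the signature
motif CQHG-X2-EC-X2-N-X4-C, allowing one mismatch at the motif's fixed
positions by default.

**Acanthoscurrin-like.** Gly fraction ≥ 0.4 over the C-terminal 30
residues.

**Dae2 and c-type lysozyme** have no compact printed signature, so they are
recognized by homology against a reference set (coverage ≥ 0.7, identity
≥ 0.4 by default).

**Vocabulary classifier.** Hit descriptions are scanned best-hit-first for
keywords (case- and punctuation-insensitive, whole-token matching); within
a description the highest-precedence keyword wins, and if the best hit
yields no keyword the scan falls through the remaining hits in score order.
The shipped vocabulary (~60 entries, immunity terms ranked first) is a seed
meant to be edited; precedence is file order. The algorithm, not the word
list, is the contract.

## Peptide physicochemistry

Average and monoisotopic masses use Biopython's standard residue tables
plus one water; each disulfide bridge subtracts two hydrogens (2 × 1.00794
Da average, 2 × 1.007825 Da monoisotopic). Report rounding is to the
nearest dalton. Net charge is a Henderson–Hasselbalch sum over termini and
ionizable side chains with a classic textbook pKa set (N-terminus 9.6,
C-terminus 2.35; K 10.5, R 12.5, H 6.5, D 3.9, E 4.1, C 8.3, Y 10.1),
exposed as `peptide_chem.PKA`. The strong termini values keep uncharged
homopolymers neutral at pH 7, which EMBOSS's weaker N-terminal pKa does
not; any standard set preserves the qualitative statement that matters
here — mature defensins are strongly cationic at neutral pH. Free
cysteines count as (weak) acids; the charge of an oxidized peptide is
therefore slightly underestimated — acceptable for a qualitative
cationicity readout. Concentration conversion is µg/mL = µM × Da × 1e-3.

## MIC assay

A dilution series is the exact geometric ladder top/factor^i; with the
default 16 points and factor 2, a 250 µM top reaches 7.63 nM (reported as
8 nM at integer rounding). Background subtraction removes the mean
medium-only blank series, floored at zero. The growth metric defaults to
the peak background-corrected OD (robust to when growth starts); AUC is
available. "100% inhibition" is operationalized as a growth metric ≤ 10% of
the growth control — the assay literature states full inhibition without a
numeric criterion, and 10% absorbs baseline noise while remaining far below
any real growth curve. The MIC is the lowest concentration of the
contiguous fully-inhibited top segment of the ladder; isolated growth above
an inhibited well (a skipped well, contamination) triggers a warning rather
than a silent fix, and censored results (">top") are first-class values. A
plate whose growth control does not grow is an invalid assay and raises.

## Synthetic data: what it emulates, and what it does not

The generators produce the three inputs the pipeline needs, from explicit
seeded configs. The defaults state the scenario the package is built
around: a 4-condition design (unfed; water-fed; *M. luteus*-fed;
*Pantoea*-fed) with 3 replicates, a strong biphasic feeding effect and no
bacteria-versus-water effect.

**Transcript pool.** Each planted AMP is a full prepro protein — signal
peptide (charged n-region, 10-residue hydrophobic core, A-X-A cleavage)
plus a mature region — encoded with random synonymous codons and flanked by
UTRs (40–300 nt). Mature regions derive from one fixed template per family
by point substitutions at 10% of unprotected positions (scaffold cysteines,
GILT motif residues, the Gly content of the acanthoscurrin tail and the
defensin's four C-terminal residues are protected). The same templates are
exposed as the homology reference set, so plants resemble references the
way real family members resemble database entries (~90% identity) instead
of being byte-copies; templates are parameterized scaffolds, not copies of
real genes. Decoys are random nucleotide sequences (GC 0.48, 300–1500 nt)
re-drawn in the rare case a six-frame translation contains a
defensin-compatible Cys scaffold. The truth table records family, prepro
protein, mature span, CDS span and, after count simulation, true
per-contrast log fold changes.

**Counts.** Base abundances are lognormal (meanlog 3, sdlog 1.5) with
planted AMPs boosted 20× into the abundant tail, weighted by transcript
length, scaled to the library size (default 1e6 reads — a deliberate
desk-scale stand-in for the tens of millions in a real library), and drawn
as gamma-Poisson with var = μ + φμ² (default φ = 0.05, a typical RNA-seq
biological dispersion). A seeded 30% of transcripts is "fed-modulated":
their means shift by ±2 log2 units (random sign, the biphasic pattern) in
all fed conditions versus unfed; bacteria-fed conditions differ from
water-fed by a separate magnitude, default 0.

**Plates.** Logistic growth N(t) = K/(1 + (K/N0 − 1)e^(−rt)) above baseline
(defaults r = 0.4 h⁻¹, K = 1.0 OD, N0 = 0.005, baseline 0.05 OD), read
every 20 min for 48 h; inhibition is a hard threshold on concentration —
wells at or above the true threshold stay at baseline. The hard threshold
makes MIC recovery exactly checkable; Gaussian read noise (default 0.005
OD) is the only stochastic element.

**What green tests do not establish.** The generators do not model read
sequencing or mapping (so mapping-rate QC is tested on synthetic rate
tables), assembly artifacts (chimeras, fragmented isoforms), genuinely
novel AMP families absent from the reference set, gene-specific dispersion,
graded dose–response near the MIC, or plate edge/drift effects. Passing
tests establish that the *methods* behave as specified on data matching
their stated assumptions — not that the heuristics (signal peptide,
vocabulary) would match trained tools on real tick sequences.

## Numerical conventions

* All thresholds are inclusive or strict exactly as stated: homology
  coverage ≥ 0.70, consolidation identity ≥ 0.95, expression mean ≥ 5
  (inclusive); |log2FC| > 1, FDR < 0.05 (strict).
* The exact NB test compares split probabilities with a 1 + 1e-10 relative
  tolerance when summing "no more likely" outcomes, avoiding
  floating-point ties.
* Dispersion floor 1e-4; logFC pseudo-count 0.5 per group mean.
* Greedy clustering order: length descending, then id ascending.
* File writers sort keys and fix float formats (2 decimals for the
  TPM summary tables), so identical seeds give identical bytes.
* Seeds: every generator consumes a single integer seed through
  `numpy.random.default_rng`; the pipeline derives stage seeds as
  seed and seed + 1.

## Known limitations

* The exact NB test with a common dispersion is anticonservative when
  per-gene dispersions vary strongly; the shipped calibration covers the
  common-dispersion regime the generator produces.
* Smith–Waterman against large reference sets is O(nm) per pair; the
  k-mer prescreen helps, but a real database search should use a dedicated
  tool and feed its tabular output into `extract_by_homology`.
* The signal-peptide heuristic ignores transmembrane segments, the
  commonest source of false positives on real data.
* `consolidate` clusters against representatives only (single-linkage to
  the representative), as greedy-incremental clusterers do; members of one
  cluster may be < 95% identical to each other.
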