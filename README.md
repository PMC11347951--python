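# guardamp

Analysis toolkit for discovering constitutively expressed ("guard")
antimicrobial peptides (AMPs) in tick midgut transcriptomes, and for
characterizing them biochemically. It is written for vector-biology and
arthropod-immunity groups who assemble a midgut transcriptome, ask which
immune effectors are already present before any microbial challenge, and
then test candidate peptides in microplate growth-inhibition assays.

The package implements the full analysis path as reusable, tested library
code, with a seeded synthetic-data module standing in for raw sequencing
reads and plate-reader exports so every stage runs and is verifiable
offline.

## What it computes

**CDS extraction** (`guardamp.cds_extraction`). Open reading frames of at
least 175 nt are scanned in all six frames (a maximal stop-free codon run;
the stop codon is excluded from the length). Coding sequences are accepted
by either of two evidence routes:

* *homology*: Smith–Waterman alignment (BLOSUM62, affine gaps 11/1) against
  a reference protein set; an ORF qualifies when its best hit covers ≥ 70%
  of the matched protein;
* *signal peptide*: ORFs starting with a methionine and ≥ 40 residues long
  are scored with a documented heuristic (n-region charge, Kyte–Doolittle
  h-region window, A-X-A–type cleavage site); the Met codon closest to the
  5′ end of the frame becomes the start codon.

Sequences ≥ 95% identical are consolidated by greedy longest-first
clustering. Expression is quantified as transcripts per million,

    TPM_i = 10^6 · (c_i/ℓ_i) / Σ_j (c_j/ℓ_j),

and a CDS is retained when its mean TPM reaches 5 in at least one
biological condition.

**Differential expression** (`guardamp.expression_stats`). Counts are
normalized with median-of-ratios size factors; a common negative-binomial
dispersion φ (var = μ + φμ²) is estimated by pooled method of moments; each
gene gets an exact conditional NB test on the normalized group sums, and
Benjamini–Hochberg FDR. A CDS is called modulated when |log2FC| > 1 and
FDR < 0.05 (strict boundaries). Mapping-rate QC excludes libraries falling
below the leave-one-out median minus 5 robust SDs — the rule that flags a
single failed library among tight replicates.

**AMP annotation** (`guardamp.annotation`). An ordered-vocabulary scan of
homology-hit descriptions assigns functional classes; sequence-signature
scanners recognize the guard-AMP families: defensins (six cysteines with
canonical C1–C4, C2–C5, C3–C6 disulfide connectivity and subtype motifs),
microplusin/ricinusin (His- and Cys-rich; type 2 has a His-rich
C-terminus), GILT thiol reductases (CXXC active site plus signature motif)
and glycine-rich acanthoscurrin-like peptides. Dae2 and c-type lysozyme are
called by homology.

**Peptide physicochemistry** (`guardamp.peptide_chem`). Average and
monoisotopic masses with the disulfide correction (−2 H per bridge),
Henderson–Hasselbalch net charge, µM → µg/mL conversion, and canonical
disulfide connectivity.

**MIC determination** (`guardamp.mic_assay`). Two-fold serial-dilution
planning, blank (medium-only) background subtraction, per-well growth
metrics, and the MIC call: the lowest concentration at which that well and
every higher concentration are fully inhibited (growth metric ≤ 10% of the
growth control); plates with no inhibition are censored as ">top".

## Worked example

Characterize the mature midgut defensin 1 and call a MIC from a simulated
dilution plate:

```python
from guardamp.peptide_chem import PeptideSpec, average_mass, net_charge
from guardamp.mic_assay import plan_dilution, subtract_background, call_mic, mic_fold_change
from guardamp.synthetic_data import generate_plate, PlateSimConfig

spec = PeptideSpec("GGYYCPFFQDKCHRHCRSFGRKAGYCGGFLKKTCICVMK", n_disulfides=3)
m = average_mass(spec)
print(f"average mass: {m.average_mass:.3f} Da (~{m.average_mass_da} Da)")
print(f"net charge at pH 7: {net_charge(spec.sequence):+.2f}")

series = plan_dilution(250.0, 16)           # 250 µM down to ~8 nM
plate = generate_plate(PlateSimConfig(top_concentration=250.0,
                                      true_inhibition_threshold=0.03, seed=1))
res = call_mic(subtract_background(plate), series)
print(f"MIC: {res.label} µM (censored: {res.censored})")
raw, sf = mic_fold_change(3.0, 0.031)
print(f"DTT fold change: {raw:.1f} (~{sf:g}-fold)")
```

prints

```
average mass: 4491.278 Da (~4491 Da)
net charge at pH 7: +7.29
MIC: 0.0305176 µM (censored: False)
DTT fold change: 96.8 (~100-fold)
```

The mass is the oxidized (3-bridge) average mass rounded to the nearest
dalton; the positive net charge reflects the cationic character defensins
need to bind bacterial membranes; the MIC lands on the dilution-grid point
directly above the simulated inhibition threshold of 0.03 µM; and the
~100-fold ratio quantifies how much reducing the disulfide bridges weakens
the peptide.

The full study flow — simulate a transcript pool and count matrix, extract
and consolidate CDSs, quantify, annotate, and test the fed-versus-unfed and
bacteria-versus-water contrasts — runs as one command:

```bash
guardamp run-all --seed 1 --out demo_run
# 48 transcripts, 8 CDSs, 8 retained; modulated: {'WF_vs_UF': 2, 'Mic_vs_WF': 0, 'Pan_vs_WF': 0}
```

Per-stage artifacts (FASTA, TSV tables, a YAML report and a parameter log)
are written into `demo_run/`. Subcommands `simulate`, `extract-cds`,
`quantify`, `annotate`, `de`, `peptide` and `mic` expose the stages
individually; see `guardamp --help`.

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from
scratch: the full synthetic pipeline (simulation → CDS extraction →
quantification → annotation → differential expression), the mature-defensin
mass calculations and a simulated MIC determination, writing its JSON
output to `--out`:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Design notes

See `docs/methods.md` for the underlying models, parameter defaults, what
the synthetic generators do and do not emulate, and known limitations.
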