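"""Seeded synthetic inputs for every pipeline stage.

Real inputs to this kind of study — midgut RNA-seq libraries, an assembled
transcript pool, and microplate OD600 grids — live in sequence archives and
plate readers.  This module generates statistically faithful stand-ins from
explicit configurations so the whole pipeline is testable offline:

* a transcript pool with planted AMP-family coding sequences (parameterized
  templates, not copies of real genes) flanked by UTRs, plus non-coding
  decoys, with a truth table recording family, mature-peptide span and true
  fold changes;
* negative-binomial count matrices over the four-condition design (unfed
  UF, water-fed WF, *M. luteus*-fed Mic, *Pantoea*-fed Pan; 3 replicates
  each) with a strong biphasic fed-versus-unfed effect and, by default, no
  bacteria-versus-water effect — the structure the study design produces;
* two-fold dilution plate grids with logistic growth below a hard
  inhibition threshold, read every 20 min for 48 h.

All randomness flows from the config seed; identical configs give
byte-identical sequence output and element-wise identical matrices.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cds_extraction import CountsMatrix
from .mic_assay import PlateAssay, Well

__all__ = [
    "TranscriptomeSimConfig",
    "CountsSimConfig",
    "PlateSimConfig",
    "TruthTable",
    "PLANTABLE_FAMILIES",
    "generate_transcriptome",
    "generate_counts",
    "generate_plate",
    "logistic_od",
    "reference_proteins",
]

CONDITIONS = ("UF", "WF", "Mic", "Pan")
FED_CONDITIONS = ("WF", "Mic", "Pan")

_AA_NO_C = "ADEFGHIKLMNPQRSTVWY"
_CODONS = {
    "A": ("GCT", "GCC", "GCA", "GCG"), "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"), "E": ("GAA", "GAG"), "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"), "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"), "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"), "M": ("ATG",),
    "N": ("AAT", "AAC"), "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"), "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"), "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",), "Y": ("TAT", "TAC"), "*": ("TAA", "TAG", "TGA"),
}

# loose defensin-scaffold screen used to reject pathological decoys
_DEFENSIN_REGEX = re.compile(r"C.{4,10}C.{1,7}C.{7,13}C.{5,11}C.{1,5}C")


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptomeSimConfig:
    n_decoys: int = 40
    planted_families: tuple[tuple[str, int], ...] = (
        ("defensin_CVMK", 1),
        ("defensin_TyrC", 1),
        ("microplusin_type1", 1),
        ("microplusin_type2", 1),
        ("dae2", 1),
        ("lysozyme_c", 1),
        ("gilt", 1),
        ("acanthoscurrin_like", 1),
    )
    utr_length_range: tuple[int, int] = (40, 300)
    gc_content: float = 0.48
    mutation_rate: float = 0.10  # divergence of plants from the family template
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_decoys < 0 or any(n < 0 for _, n in self.planted_families):
            raise ValueError("counts must be >= 0")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must lie in (0, 1)")
        if not 0 <= self.mutation_rate < 0.5:
            raise ValueError("mutation_rate must lie in [0, 0.5)")
        if self.n_decoys + sum(n for _, n in self.planted_families) == 0:
            raise ValueError("configuration generates zero transcripts")
        if self.utr_length_range[0] < 0 or self.utr_length_range[1] < self.utr_length_range[0]:
            raise ValueError("invalid UTR length range")


@dataclass(frozen=True)
class CountsSimConfig:
    conditions: tuple[str, ...] = CONDITIONS
    replicates_per_condition: int = 3
    library_size: int = 1_000_000
    nb_dispersion: float = 0.05
    fraction_fed_modulated: float = 0.3
    fed_logfc_magnitude: float = 2.0
    bacteria_logfc_magnitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_condition < 2:
            raise ValueError("differential expression needs >= 2 replicates")
        if self.nb_dispersion <= 0:
            raise ValueError("NB dispersion must be > 0")
        if not 0 <= self.fraction_fed_modulated <= 1:
            raise ValueError("fraction_fed_modulated must lie in [0, 1]")
        if self.library_size <= 0:
            raise ValueError("library size must be positive")


def _default_times() -> tuple[float, ...]:
    # every 20 min for 48 h -> 145 points
    return tuple(np.round(np.arange(0, 48 + 1e-9, 1 / 3), 6))


@dataclass(frozen=True)
class PlateSimConfig:
    top_concentration: float = 250.0  # µM
    n_points: int = 16
    dilution_factor: float = 2.0
    true_inhibition_threshold: float = 0.03  # µM
    growth_rate: float = 0.4  # per hour
    carrying_capacity: float = 1.0  # OD units above baseline
    baseline_od: float = 0.05
    inoculum_od: float = 0.005
    noise_sd: float = 0.005
    timepoints: tuple[float, ...] = field(default_factory=_default_times)
    n_blanks: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.top_concentration <= 0:
            raise ValueError("top concentration must be > 0")
        if self.n_points < 1:
            raise ValueError("need >= 1 dilution point")
        if self.dilution_factor <= 1:
            raise ValueError("dilution factor must be > 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.growth_rate <= 0 or self.carrying_capacity <= 0 or self.inoculum_od <= 0:
            raise ValueError("growth parameters must be positive")


@dataclass
class TruthTable:
    """Per-transcript ground truth for the synthetic transcriptome."""

    table: pd.DataFrame  # indexed by transcript_id

    def __post_init__(self) -> None:
        planted = self.table[~self.table["is_decoy"]]
        if planted["mature_start"].isna().any():
            raise ValueError("planted family members must carry a mature-peptide span")
        if (self.table.loc[self.table["is_decoy"], "family"] != "none").any():
            raise ValueError("decoys must have family 'none'")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.table.index)

    def planted(self) -> pd.DataFrame:
        return self.table[~self.table["is_decoy"]]


# ---------------------------------------------------------------------------
# protein templates (parameterized, synthetic — not copies of real genes)
# ---------------------------------------------------------------------------

def _signal_peptide(rng: np.random.Generator) -> str:
    """n-region with positive charge, 10-residue h-region, A-X-A cleavage."""
    n_region = "M" + "".join(rng.choice(list("KR"), 2)) + "".join(
        rng.choice(list("STNQ"), 2)
    )
    h_region = "".join(rng.choice(list("LIVFA"), 10))
    cleavage = "A" + str(rng.choice(list("QSTN"))) + "A"
    return n_region + h_region + cleavage  # 18 residues, cleavage after the last A


def _filler(rng: np.random.Generator, n: int, alphabet: str = _AA_NO_C) -> str:
    return "".join(rng.choice(list(alphabet), n)) if n > 0 else ""


def _mature_defensin(rng: np.random.Generator, subtype: str) -> str:
    """Six-cysteine scaffold with the characterized inter-Cys gaps (7,4,10,8,2)."""
    gaps = (7, 4, 10, 8, 2)
    cationic = _AA_NO_C + "KKRR"  # bias toward cationicity
    parts = [_filler(rng, int(rng.integers(2, 5)), cationic)]
    for gap in gaps:
        parts.append("C")
        parts.append(_filler(rng, gap - 1, cationic))
    parts.append("C")
    tail = "VMK" if subtype == "CVMK" else "Y" + _filler(rng, 2, "SRTK")
    return "".join(parts) + tail


def _mature_microplusin(rng: np.random.Generator, his_tail: bool) -> str:
    """His-rich, six-cysteine peptide; type 2 carries a His-rich C-terminus."""
    body_alphabet = "ADEFGIKLMNQRSTVY" + "HHHHH"  # ~24% His
    gaps = (8, 12, 9, 14, 10)
    while True:
        parts = [_filler(rng, 5, body_alphabet)]
        for gap in gaps:
            parts.append("C")
            parts.append(_filler(rng, gap - 1, body_alphabet))
        parts.append("C")
        core = "".join(parts)
        if his_tail:
            tail = "".join(rng.choice(list("HHHHHGSAND"), 22))
        else:
            tail = _filler(rng, 12, "ADEFGIKLMNQRSTVY")
        peptide = core + tail
        # construction guarantees the stated His content, redrawing rare misses
        if peptide.count("H") / len(peptide) >= 0.15:
            if not his_tail or peptide[-25:].count("H") / 25 >= 0.30:
                return peptide


def _mature_gilt(rng: np.random.Generator) -> str:
    """Thiol reductase-like: CXXC active site plus the GILT signature motif."""
    plain = _AA_NO_C
    signature = "CQHG" + _filler(rng, 2, plain) + "EC" + _filler(rng, 2, plain) + \
        "N" + _filler(rng, 4, plain) + "C"
    return (
        _filler(rng, 20, plain)
        + "CGHC"  # active site
        + _filler(rng, 30, plain)
        + signature
        + _filler(rng, 40, plain)
    )


def _mature_acanthoscurrin(rng: np.random.Generator) -> str:
    body = _filler(rng, 35, _AA_NO_C)
    tail = "".join(rng.choice(list("GGGGGAS"), 30))  # ~0.6 Gly in the last 30
    return body + tail


def _mature_generic(rng: np.random.Generator, length: int) -> str:
    return _filler(rng, length, _AA_NO_C + "C")


def _mature_for(family: str, rng: np.random.Generator) -> str:
    if family == "defensin_CVMK":
        return _mature_defensin(rng, "CVMK")
    if family in ("defensin_TyrC", "defensin"):
        return _mature_defensin(rng, "TyrC")
    if family == "microplusin_type1":
        return _mature_microplusin(rng, his_tail=False)
    if family == "microplusin_type2":
        return _mature_microplusin(rng, his_tail=True)
    if family == "gilt":
        return _mature_gilt(rng)
    if family == "acanthoscurrin_like":
        return _mature_acanthoscurrin(rng)
    if family == "dae2":
        return _mature_generic(rng, 140)
    if family == "lysozyme_c":
        return _mature_generic(rng, 120)
    raise ValueError(f"unknown plantable family {family!r}")


PLANTABLE_FAMILIES = (
    "defensin_CVMK",
    "defensin_TyrC",
    "microplusin_type1",
    "microplusin_type2",
    "dae2",
    "lysozyme_c",
    "gilt",
    "acanthoscurrin_like",
)

# residues never mutated when deriving a plant from its family template:
# scaffold cysteines, the GILT motif letters, and the Gly content that
# defines the acanthoscurrin-like tail
_PROTECTED = {
    "defensin_CVMK": set("C"),
    "defensin_TyrC": set("C"),
    "microplusin_type1": set("CH"),
    "microplusin_type2": set("CH"),
    "gilt": set("CQHGEN"),
    "acanthoscurrin_like": set("CG"),
    "dae2": set(),
    "lysozyme_c": set(),
}
# the subtype-bearing C-terminal residues of a defensin are kept intact
_PROTECT_TAIL = {"defensin_CVMK": 4, "defensin_TyrC": 4}


def _mutate(protein: str, family: str, rate: float, rng: np.random.Generator) -> str:
    protected = _PROTECTED[family]
    tail = _PROTECT_TAIL.get(family, 0)
    out = []
    for i, aa in enumerate(protein):
        if aa in protected or (tail and i >= len(protein) - tail):
            out.append(aa)
        elif rng.random() < rate:
            out.append(str(rng.choice(list(_AA_NO_C))))  # never introduces Cys
        else:
            out.append(aa)
    return "".join(out)


def family_label(plant_name: str) -> str:
    """Collapse plant template names to annotation family labels."""
    if plant_name.startswith("defensin"):
        return "defensin"
    return plant_name


def _family_template(family: str) -> str:
    """Fixed mature-region template per family (stable across configs)."""
    idx = PLANTABLE_FAMILIES.index(family if family in PLANTABLE_FAMILIES else "defensin_TyrC")
    return _mature_for(family, np.random.default_rng(1000 + idx))


def reference_proteins() -> dict[str, str]:
    """Fixed synthetic reference protein set, one template per family.

    Stands in for the homology databases used in real annotation runs;
    planted transcripts diverge from these templates by the configured
    mutation rate, so the homology-only families (Dae2, c-type lysozyme)
    are genuinely recognized by alignment rather than by construction.
    Proteins are full prepro sequences (signal peptide + mature region).
    """
    refs = {}
    for i, fam in enumerate(PLANTABLE_FAMILIES):
        sig = _signal_peptide(np.random.default_rng(2000 + i))
        refs[f"ref_{fam}"] = sig + _family_template(fam)
    return refs


# ---------------------------------------------------------------------------
# transcript pool
# ---------------------------------------------------------------------------

def _encode(protein: str, rng: np.random.Generator) -> str:
    codons = [str(rng.choice(_CODONS[aa])) for aa in protein]
    codons.append(str(rng.choice(_CODONS["*"])))
    return "".join(codons)


def _random_nt(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), n, p=p))


def _decoy_is_clean(seq: str) -> bool:
    """Reject decoys whose six-frame translation contains a defensin scaffold."""
    for s in (seq, str(Seq(seq).reverse_complement())):
        for frame in range(3):
            protein = str(Seq(s[frame : frame + 3 * ((len(s) - frame) // 3)]).translate())
            for piece in protein.split("*"):
                if _DEFENSIN_REGEX.search(piece):
                    return False
    return True


def generate_transcriptome(
    config: TranscriptomeSimConfig,
) -> tuple[list[SeqRecord], TruthTable]:
    """Transcript pool with planted AMP CDSs and non-coding decoys.

    Planted transcripts carry a full CDS (Met start through stop codon)
    flanked by 5' and 3' UTRs; the truth table records the CDS span on the
    transcript, the prepro protein, and the mature-peptide span within it.
    """
    rng = np.random.default_rng(config.seed)
    records: list[SeqRecord] = []
    rows: list[dict] = []

    for fam, count in config.planted_families:
        template = _family_template(fam)
        for i in range(count):
            sig = _signal_peptide(rng)
            mature = _mutate(template, fam, config.mutation_rate, rng)
            protein = sig + mature
            cds_nt = _encode(protein, rng)
            lo, hi = config.utr_length_range
            utr5 = _random_nt(rng, int(rng.integers(lo, hi + 1)), config.gc_content)
            utr3 = _random_nt(rng, int(rng.integers(lo, hi + 1)), config.gc_content)
            seq = utr5 + cds_nt + utr3
            tid = f"amp_{fam}_{i}"
            records.append(SeqRecord(Seq(seq), id=tid, description=""))
            rows.append(
                dict(
                    transcript_id=tid,
                    family=family_label(fam),
                    plant_template=fam,
                    is_decoy=False,
                    protein=protein,
                    mature_start=len(sig),  # 0-based protein coords
                    mature_end=len(protein),
                    cds_start=len(utr5),
                    cds_end=len(utr5) + len(cds_nt),
                )
            )

    for i in range(config.n_decoys):
        length = int(rng.integers(300, 1500))
        seq = _random_nt(rng, length, config.gc_content)
        while not _decoy_is_clean(seq):  # pragma: no cover - rare rejection
            seq = _random_nt(rng, length, config.gc_content)
        tid = f"decoy_{i}"
        records.append(SeqRecord(Seq(seq), id=tid, description=""))
        rows.append(
            dict(
                transcript_id=tid,
                family="none",
                plant_template="",
                is_decoy=True,
                protein="",
                mature_start=np.nan,
                mature_end=np.nan,
                cds_start=np.nan,
                cds_end=np.nan,
            )
        )

    table = pd.DataFrame(rows).set_index("transcript_id")
    return records, TruthTable(table=table)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def generate_counts(
    truth: TruthTable,
    config: CountsSimConfig,
    transcript_lengths: dict[str, int] | None = None,
) -> tuple[CountsMatrix, TruthTable]:
    """NB-distributed counts over the four-condition, replicated design.

    A seeded fraction of transcripts is "fed-modulated": their mean shifts
    by ``fed_logfc_magnitude`` (random sign, half up / half down — the
    biphasic pattern feeding induces) in all fed conditions relative to
    unfed.  Bacteria-fed conditions differ from water-fed by
    ``bacteria_logfc_magnitude`` (default 0: no immune induction).  Counts
    are gamma-Poisson draws with var = mu + phi * mu^2.  True per-contrast
    log2 fold changes are written back into the truth table.
    """
    rng = np.random.default_rng(config.seed)
    ids = truth.transcript_ids
    n = len(ids)

    # base abundance: lognormal spread; planted AMPs sit in the abundant tail
    base = np.exp(rng.normal(3.0, 1.5, size=n))
    planted_mask = (~truth.table["is_decoy"]).to_numpy()
    base[planted_mask] *= 20.0

    lengths = np.array(
        [
            (transcript_lengths or {}).get(
                t, int(truth.table.loc[t, "cds_end"]) if planted_mask[i] else 1000
            )
            for i, t in enumerate(ids)
        ],
        dtype=float,
    )

    n_mod = int(round(config.fraction_fed_modulated * n))
    mod_idx = rng.choice(n, size=n_mod, replace=False)
    signs = np.zeros(n)
    signs[mod_idx] = rng.choice([-1.0, 1.0], size=n_mod)

    fed_factor = 2.0 ** (signs * config.fed_logfc_magnitude)
    bact_factor = 2.0 ** (signs * config.bacteria_logfc_magnitude)

    cond_factor = {c: np.ones(n) for c in config.conditions}
    for c in config.conditions:
        if c in FED_CONDITIONS:
            cond_factor[c] = fed_factor.copy()
        if c in ("Mic", "Pan"):
            cond_factor[c] = cond_factor[c] * bact_factor

    columns = {}
    conditions = {}
    for c in config.conditions:
        weights = base * cond_factor[c] * lengths / 1000.0
        mu = config.library_size * weights / weights.sum()
        for r in range(1, config.replicates_per_condition + 1):
            lib = f"{c}{r}"
            lam = rng.gamma(shape=1.0 / config.nb_dispersion,
                            scale=mu * config.nb_dispersion)
            columns[lib] = rng.poisson(lam)
            conditions[lib] = c

    counts = pd.DataFrame(columns, index=ids)

    table = truth.table.copy()
    table["true_logfc_WF_vs_UF"] = np.log2(cond_factor["WF"] / cond_factor["UF"]) \
        if "WF" in cond_factor and "UF" in cond_factor else 0.0
    for c in ("Mic", "Pan"):
        if c in cond_factor and "WF" in cond_factor:
            table[f"true_logfc_{c}_vs_WF"] = np.log2(cond_factor[c] / cond_factor["WF"])
    return CountsMatrix(counts=counts, conditions=conditions), TruthTable(table=table)


# ---------------------------------------------------------------------------
# plates
# ---------------------------------------------------------------------------

def logistic_od(t, growth_rate: float, carrying_capacity: float, inoculum_od: float):
    """Closed-form logistic growth curve N(t) = K / (1 + (K/N0 - 1) e^(-rt))."""
    t = np.asarray(t, dtype=float)
    ratio = (carrying_capacity - inoculum_od) / inoculum_od
    return carrying_capacity / (1.0 + ratio * np.exp(-growth_rate * t))


def generate_plate(config: PlateSimConfig) -> PlateAssay:
    """Dilution-series plate with hard-threshold inhibition.

    Wells at a concentration >= the true inhibition threshold stay at
    baseline OD (plus noise); wells below it follow logistic growth.  A
    growth control (no peptide) and medium-only blanks are included.
    """
    rng = np.random.default_rng(config.seed)
    times = np.asarray(config.timepoints, dtype=float)
    growth = logistic_od(
        times, config.growth_rate, config.carrying_capacity, config.inoculum_od
    )

    def noise() -> np.ndarray:
        if config.noise_sd == 0:
            return np.zeros_like(times)
        return rng.normal(0.0, config.noise_sd, size=times.shape)

    wells: list[Well] = []
    conc = config.top_concentration
    for _ in range(config.n_points):
        if conc >= config.true_inhibition_threshold:
            od = config.baseline_od + noise()
        else:
            od = config.baseline_od + growth + noise()
        wells.append(Well(concentration=conc, role="sample", od=np.maximum(od, 0.0)))
        conc /= config.dilution_factor
    wells.append(
        Well(
            concentration=0.0,
            role="growth-control",
            od=np.maximum(config.baseline_od + growth + noise(), 0.0),
        )
    )
    for _ in range(config.n_blanks):
        wells.append(
            Well(
                concentration=0.0,
                role="blank",
                od=np.maximum(config.baseline_od + noise(), 0.0),
            )
        )
    return PlateAssay(times=times, wells=wells)
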