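"""Functional annotation and AMP family signature detection.

Two complementary layers:

* an ordered-vocabulary classifier that scans the descriptions of homology
  hits (best hit first) for keywords and returns the functional class of
  the highest-precedence keyword found — a reimplementation of the classic
  in-house keyword-scan annotators used for arthropod transcriptomes;
* sequence-signature scanners for the antimicrobial peptide families that
  guard the unfed tick midgut: defensins (six-cysteine scaffold, three
  canonical disulfide bridges), microplusin/ricinusin (His- and Cys-rich,
  type 2 distinguished by a His-rich C-terminus), GILT (thiol reductase
  with a CXXC active site plus signature motif) and glycine-rich
  acanthoscurrin-like peptides.  Dae2 and c-type lysozyme carry no printed
  de novo signature and are called by homology against a reference set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .cds_extraction import TpmMatrix, match_homology
from .peptide_chem import canonical_connectivity

__all__ = [
    "VocabularyEntry",
    "AmpAnnotation",
    "DEFAULT_VOCABULARY",
    "DEFENSIN_GAP_WINDOWS",
    "classify_by_vocabulary",
    "scan_defensin",
    "scan_microplusin",
    "scan_gilt",
    "scan_glycine_rich",
    "homology_family_call",
    "annotate_protein",
    "class_abundance",
    "load_vocabulary",
    "save_vocabulary",
]

FAMILIES = (
    "defensin",
    "microplusin_type1",
    "microplusin_type2",
    "dae2",
    "lysozyme_c",
    "acanthoscurrin_like",
    "gilt",
    "none",
)


@dataclass(frozen=True)
class VocabularyEntry:
    keyword: str  # lower-case token or phrase
    functional_class: str
    precedence: int  # smaller = higher priority


@dataclass(frozen=True)
class AmpAnnotation:
    cds_id: str
    family: str
    subtype: str | None = None
    evidence: str = ""
    cys_positions: tuple[int, ...] = ()  # 1-based residue indices
    connectivity: tuple[tuple[int, int], ...] = ()


# Seed vocabulary: the algorithm (ordered keyword scan) is the contract; the
# word list is user-editable via load_vocabulary()/save_vocabulary().
# Precedence = position in this list.
_SEED_VOCAB = [
    # immunity first: an AMP description wins over generic enzyme words
    ("defensin", "Immunity"),
    ("microplusin", "Immunity"),
    ("ricinusin", "Immunity"),
    ("hebraein", "Immunity"),
    ("amidase effector", "Immunity"),
    ("dae2", "Immunity"),
    ("lysozyme", "Immunity"),
    ("acanthoscurrin", "Immunity"),
    ("thiol reductase", "Immunity"),
    ("gilt", "Immunity"),
    ("antimicrobial", "Immunity"),
    ("peptidoglycan recognition", "Immunity"),
    ("thioester-containing protein", "Immunity"),
    ("clip domain serine protease", "Immunity"),
    ("ficolin", "Immunity"),
    ("lectin", "Immunity"),
    ("cathepsin", "Proteases"),
    ("trypsin", "Proteases"),
    ("chymotrypsin", "Proteases"),
    ("serine protease", "Proteases"),
    ("metalloprotease", "Proteases"),
    ("carboxypeptidase", "Proteases"),
    ("aminopeptidase", "Proteases"),
    ("legumain", "Proteases"),
    ("protease inhibitor", "Protease inhibitors"),
    ("serpin", "Protease inhibitors"),
    ("cystatin", "Protease inhibitors"),
    ("kunitz", "Protease inhibitors"),
    ("ferritin", "Metabolism, iron"),
    ("transferrin", "Metabolism, iron"),
    ("heme-binding", "Metabolism, iron"),
    ("hemelipoglycoprotein", "Metabolism, iron"),
    ("vitellogenin", "Metabolism, iron"),
    ("glutathione s-transferase", "Detoxification"),
    ("cytochrome p450", "Detoxification"),
    ("superoxide dismutase", "Detoxification"),
    ("peroxidase", "Detoxification"),
    ("catalase", "Detoxification"),
    ("transporter", "Transporters"),
    ("channel", "Transporters"),
    ("aquaporin", "Transporters"),
    ("atpase", "Transporters"),
    ("glycosidase", "Metabolism, carbohydrate"),
    ("glucosidase", "Metabolism, carbohydrate"),
    ("chitinase", "Metabolism, carbohydrate"),
    ("lipase", "Metabolism, lipid"),
    ("phospholipase", "Metabolism, lipid"),
    ("apolipoprotein", "Metabolism, lipid"),
    ("kinase", "Signal transduction"),
    ("phosphatase", "Signal transduction"),
    ("g protein", "Signal transduction"),
    ("ribosomal protein", "Protein synthesis"),
    ("elongation factor", "Protein synthesis"),
    ("trna", "Protein synthesis"),
    ("histone", "Nuclear regulation"),
    ("transcription factor", "Nuclear regulation"),
    ("zinc finger", "Nuclear regulation"),
    ("tubulin", "Cytoskeletal"),
    ("actin", "Cytoskeletal"),
    ("myosin", "Cytoskeletal"),
    ("collagen", "Extracellular matrix"),
    ("mucin", "Extracellular matrix"),
    ("hypothetical", "Unknown"),
    ("uncharacterized", "Unknown"),
]

DEFAULT_VOCABULARY: tuple[VocabularyEntry, ...] = tuple(
    VocabularyEntry(kw, cls, i) for i, (kw, cls) in enumerate(_SEED_VOCAB)
)


def load_vocabulary(path) -> list[VocabularyEntry]:
    """Read a vocabulary TSV (keyword, class, precedence)."""
    df = pd.read_csv(path, sep="\t")
    return [
        VocabularyEntry(str(r.keyword).lower(), str(r.functional_class), int(r.precedence))
        for r in df.itertuples()
    ]


def save_vocabulary(vocabulary, path) -> None:
    pd.DataFrame(
        [(v.keyword, v.functional_class, v.precedence) for v in vocabulary],
        columns=["keyword", "functional_class", "precedence"],
    ).to_csv(path, sep="\t", index=False)


def _normalize(text: str) -> str:
    # case- and punctuation-insensitive token stream
    return " " + re.sub(r"[^a-z0-9]+", " ", text.lower()).strip() + " "


def classify_by_vocabulary(
    hit_descriptions: list[str],
    vocabulary: "list[VocabularyEntry] | tuple[VocabularyEntry, ...]" = DEFAULT_VOCABULARY,
) -> str:
    """Functional class from homology-hit descriptions, best hit first.

    Within a description, the highest-precedence (lowest rank) keyword wins;
    when the best hit's description contains no vocabulary keyword, lower-
    ranked hits are consulted in order.  No keyword anywhere -> "unknown".
    """
    if not vocabulary:
        raise ValueError("empty vocabulary")
    for description in hit_descriptions:
        text = _normalize(description)
        found = [
            v for v in vocabulary
            if " " + re.sub(r"[^a-z0-9]+", " ", v.keyword.lower()).strip() + " " in text
        ]
        if found:
            return min(found, key=lambda v: v.precedence).functional_class
    return "unknown"


# ---------------------------------------------------------------------------
# defensin scaffold
# ---------------------------------------------------------------------------

# Inter-cysteine gap windows for the 6-Cys scaffold.  Both characterized
# midgut defensins share gaps (7, 4, 10, 8, 2); the windows allow +/- 3.
DEFENSIN_GAP_WINDOWS: tuple[tuple[int, int], ...] = (
    (4, 10),
    (1, 7),
    (7, 13),
    (5, 11),
    (1, 5),
)


def _cys_positions(protein: str) -> tuple[int, ...]:
    return tuple(i + 1 for i, aa in enumerate(protein) if aa == "C")


def scan_defensin(
    mature_protein: str,
    cds_id: str = "",
    gap_windows: tuple[tuple[int, int], ...] = DEFENSIN_GAP_WINDOWS,
) -> AmpAnnotation:
    """Detect the defensin 6-cysteine scaffold in a mature peptide.

    Requires a 30-60 residue peptide with exactly six cysteines whose
    consecutive gaps fall within the configured windows.  Disulfide
    connectivity is assigned canonically (C1-C4, C2-C5, C3-C6).  Subtypes:
    ``CVMK_terminal`` when the peptide ends in CVMK, and
    ``Tyr_adjacent_terminal_Cys`` when the residue immediately after the
    last cysteine is a tyrosine.
    """
    protein = mature_protein.upper().rstrip("*")
    none = AmpAnnotation(cds_id=cds_id, family="none")
    if not 30 <= len(protein) <= 60:
        return none
    cys = _cys_positions(protein)
    if len(cys) != 6:
        return none
    gaps = [b - a for a, b in zip(cys, cys[1:])]
    for gap, (lo, hi) in zip(gaps, gap_windows):
        if not lo <= gap <= hi:
            return none
    subtype = None
    if protein.endswith("CVMK"):
        subtype = "CVMK_terminal"
    elif cys[-1] < len(protein) and protein[cys[-1]] == "Y":
        subtype = "Tyr_adjacent_terminal_Cys"
    return AmpAnnotation(
        cds_id=cds_id,
        family="defensin",
        subtype=subtype,
        evidence=f"6-Cys scaffold, gaps {gaps}",
        cys_positions=cys,
        connectivity=tuple(canonical_connectivity(cys)),
    )


def scan_microplusin(
    protein: str,
    cds_id: str = "",
    min_his_fraction: float = 0.12,
    tail_his_fraction: float = 0.25,
    tail_length: int = 25,
) -> AmpAnnotation:
    """Detect His- and Cys-rich microplusin/ricinusin-type peptides.

    Requires >= 60 residues, overall His fraction >= ``min_his_fraction``
    and a six-cysteine pattern.  Type 2 (microplusin/hebraein-like) is
    distinguished by a histidine-rich C-terminus.
    """
    protein = protein.upper().rstrip("*")
    none = AmpAnnotation(cds_id=cds_id, family="none")
    if len(protein) < 60:
        return none
    his_frac = protein.count("H") / len(protein)
    cys = _cys_positions(protein)
    if his_frac < min_his_fraction or len(cys) != 6:
        return none
    tail = protein[-tail_length:]
    tail_frac = tail.count("H") / len(tail)
    family = "microplusin_type2" if tail_frac >= tail_his_fraction else "microplusin_type1"
    return AmpAnnotation(
        cds_id=cds_id,
        family=family,
        evidence=f"His fraction {his_frac:.3f}, C-terminal His fraction {tail_frac:.3f}",
        cys_positions=cys,
    )


GILT_SIGNATURE = "CQHGXXECXXNXXXXC"  # X = any residue


def _motif_mismatches(window: str, motif: str) -> int:
    return sum(1 for w, m in zip(window, motif) if m != "X" and w != m)


def scan_gilt(
    protein: str,
    cds_id: str = "",
    signature: str = GILT_SIGNATURE,
    max_mismatches: int = 1,
) -> AmpAnnotation:
    """Detect GILT thiol reductases: CXXC active site plus signature motif.

    Both motifs are required.  The signature is matched allowing up to
    ``max_mismatches`` substitutions at its fixed (non-X) positions.
    """
    protein = protein.upper().rstrip("*")
    none = AmpAnnotation(cds_id=cds_id, family="none")
    if len(protein) < 100:
        return none
    active = re.search(r"C..C", protein)
    if active is None:
        return none
    k = len(signature)
    for i in range(len(protein) - k + 1):
        if _motif_mismatches(protein[i : i + k], signature) <= max_mismatches:
            return AmpAnnotation(
                cds_id=cds_id,
                family="gilt",
                evidence=(
                    f"CXXC at {active.start() + 1}, signature at {i + 1}"
                ),
            )
    return none


def scan_glycine_rich(
    protein: str,
    cds_id: str = "",
    tail_length: int = 30,
    min_gly_fraction: float = 0.4,
) -> AmpAnnotation:
    """Detect acanthoscurrin-like peptides by a glycine-rich C-terminus."""
    protein = protein.upper().rstrip("*")
    none = AmpAnnotation(cds_id=cds_id, family="none")
    if len(protein) < 40:
        return none
    tail = protein[-tail_length:]
    frac = tail.count("G") / len(tail)
    if frac >= min_gly_fraction:
        return AmpAnnotation(
            cds_id=cds_id,
            family="acanthoscurrin_like",
            evidence=f"C-terminal Gly fraction {frac:.3f}",
        )
    return none


def homology_family_call(
    protein: str,
    references: dict[str, str],
    family_of: dict[str, str],
    cds_id: str = "",
    min_coverage: float = 0.7,
    min_identity: float = 0.4,
) -> AmpAnnotation:
    """Homology-only family call (Dae2, c-type lysozyme).

    These families have no compact printed sequence signature, so they are
    recognized by alignment against a reference set; ``family_of`` maps
    reference ids to family labels.
    """
    hits = match_homology(protein, references, query_id=cds_id)
    for hit in hits:
        fam = family_of.get(hit.subject_id)
        if fam and hit.subject_coverage >= min_coverage and hit.identity >= min_identity:
            return AmpAnnotation(
                cds_id=cds_id,
                family=fam,
                evidence=(
                    f"homology to {hit.subject_id}: coverage "
                    f"{hit.subject_coverage:.2f}, identity {hit.identity:.2f}"
                ),
            )
    return AmpAnnotation(cds_id=cds_id, family="none")


def annotate_protein(
    protein: str,
    cds_id: str = "",
    mature_protein: str | None = None,
    homology_references: dict[str, str] | None = None,
    homology_families: dict[str, str] | None = None,
) -> AmpAnnotation:
    """Run all family scanners on one protein; first positive call wins.

    The defensin scanner runs on the mature peptide when a mature span is
    known (signal/pro region removed); the remaining scanners operate on
    the full protein.
    """
    mature = mature_protein if mature_protein is not None else protein
    for ann in (
        scan_defensin(mature, cds_id),
        scan_microplusin(protein, cds_id),
        scan_gilt(protein, cds_id),
        scan_glycine_rich(protein, cds_id),
    ):
        if ann.family != "none":
            return ann
    if homology_references and homology_families:
        ann = homology_family_call(protein, homology_references, homology_families, cds_id)
        if ann.family != "none":
            return ann
    return AmpAnnotation(cds_id=cds_id, family="none")


def class_abundance(tpm: TpmMatrix, classes: dict[str, str]) -> pd.DataFrame:
    """Per-condition TPM share of each functional class, in percent.

    Every CDS must carry a class label.  For each condition the replicate-
    mean TPM is summed per class and expressed as a percentage of the total;
    columns sum to 100.
    """
    missing = set(map(str, tpm.tpm.index)) - set(classes)
    if missing:
        raise ValueError(f"CDSs without a class label: {sorted(missing)[:5]} ...")
    means = tpm.condition_means()
    labels = pd.Series({i: classes[str(i)] for i in means.index})
    grouped = means.groupby(labels).sum()
    return 100.0 * grouped / grouped.sum(axis=0)
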