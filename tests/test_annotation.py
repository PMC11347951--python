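"""AMP family signature scanners and the ordered-vocabulary classifier."""

import numpy as np
import pandas as pd
import pytest

from guardamp.annotation import (
    DEFAULT_VOCABULARY,
    VocabularyEntry,
    class_abundance,
    classify_by_vocabulary,
    homology_family_call,
    scan_defensin,
    scan_gilt,
    scan_glycine_rich,
    scan_microplusin,
)
from guardamp.cds_extraction import TpmMatrix, find_orfs

DEFENSIN_1 = "GGYYCPFFQDKCHRHCRSFGRKAGYCGGFLKKTCICVMK"
DEFENSIN_8 = "GFGCPFNQGACHRHCRSIGRRGGYCAGFLKQTCTCYSR"


# ---------------------------------------------------------------------------
# vocabulary classifier
# ---------------------------------------------------------------------------

def test_vocabulary_no_hits_is_unknown():
    assert classify_by_vocabulary([]) == "unknown"
    assert classify_by_vocabulary(["a mysterious sequence"]) == "unknown"


def test_vocabulary_single_keyword():
    assert classify_by_vocabulary(["putative defensin precursor"]) == "Immunity"


def test_vocabulary_precedence_within_description():
    """When a description holds several keywords, the top-ranked one wins."""
    desc = "ABC transporter domain fused to a defensin-like region"
    assert classify_by_vocabulary([desc]) == "Immunity"
    # and the ordering is the vocabulary's, not the description's
    vocab = [
        VocabularyEntry("transporter", "Transporters", 0),
        VocabularyEntry("defensin", "Immunity", 1),
    ]
    assert classify_by_vocabulary([desc], vocab) == "Transporters"


def test_vocabulary_falls_through_hits_in_order():
    descs = ["uncharted protein x17", "cytochrome p450 3a4"]
    assert classify_by_vocabulary(descs) == "Detoxification"


def test_vocabulary_case_and_punctuation_invariance():
    for desc in ("DEFENSIN!", "(defensin)", "Putative DEFENSIN, precursor."):
        assert classify_by_vocabulary([desc]) == "Immunity"


def test_vocabulary_requires_entries():
    with pytest.raises(ValueError):
        classify_by_vocabulary(["defensin"], [])


# ---------------------------------------------------------------------------
# defensin scaffold
# ---------------------------------------------------------------------------

def test_defensin_scan_printed_type1():
    ann = scan_defensin(DEFENSIN_1)
    assert ann.family == "defensin"
    assert ann.cys_positions == (5, 12, 16, 26, 34, 36)
    assert ann.connectivity == ((5, 26), (12, 34), (16, 36))
    assert ann.subtype == "CVMK_terminal"


def test_defensin_scan_printed_type8():
    ann = scan_defensin(DEFENSIN_8)
    assert ann.family == "defensin"
    assert ann.cys_positions == (4, 11, 15, 25, 33, 35)
    assert ann.connectivity == ((4, 25), (11, 33), (15, 35))
    assert ann.subtype == "Tyr_adjacent_terminal_Cys"


def test_defensin_scan_rejects_wrong_scaffolds():
    five_cys = DEFENSIN_1.replace("C", "S", 1)
    assert scan_defensin(five_cys).family == "none"
    assert scan_defensin("A" * 45).family == "none"
    assert scan_defensin(DEFENSIN_1 + "A" * 40).family == "none"  # too long
    # collapsed spacing: all six Cys adjacent
    assert scan_defensin("G" * 20 + "CCCCCC" + "G" * 10).family == "none"


def test_defensin_scanner_on_planted_and_decoys(demo_transcriptome):
    """Sensitivity 1 on planted defensins; no calls on decoy ORF windows."""
    transcripts, truth = demo_transcriptome
    planted = truth.planted()
    defensins = planted[planted["family"] == "defensin"]
    assert len(defensins) == 2
    for _, row in defensins.iterrows():
        mature = row["protein"][int(row["mature_start"]) : int(row["mature_end"])]
        assert scan_defensin(mature).family == "defensin"
    for rec in transcripts:
        if not rec.id.startswith("decoy"):
            continue
        for orf in find_orfs(rec, min_nt=90):
            protein = orf.protein
            for i in range(0, max(1, len(protein) - 45), 5):
                assert scan_defensin(protein[i : i + 45]).family == "none"


# ---------------------------------------------------------------------------
# microplusin / GILT / glycine-rich
# ---------------------------------------------------------------------------

def test_microplusin_threshold_arithmetic_type1():
    # 80-mer, 11 His (fraction 0.1375 >= 0.12), 6 Cys, His-free tail
    residues = list("A" * 80)
    for i in range(11):
        residues[i] = "H"
    for i in (12, 20, 30, 40, 48, 54):
        residues[i] = "C"
    peptide = "".join(residues)
    assert peptide.count("C") == 6 and len(peptide) == 80
    assert peptide.count("H") / 80 >= 0.12
    assert peptide[-25:].count("H") / 25 < 0.25
    assert scan_microplusin(peptide).family == "microplusin_type1"


def test_microplusin_type2_his_rich_tail(demo_transcriptome):
    _, truth = demo_transcriptome
    planted = truth.planted()
    for _, row in planted[planted["family"] == "microplusin_type2"].iterrows():
        mature = row["protein"][int(row["mature_start"]) :]
        assert scan_microplusin(mature).family == "microplusin_type2"


def test_microplusin_rejects_his_free_protein():
    assert scan_microplusin("ACDEFG" * 15).family == "none"


def test_gilt_requires_both_motifs():
    plain = "ADEFGIKLMRSTVWY"
    backbone = (plain * 10)[:90]
    signature = "CQHGLAECIKNADEF" + "C"
    with_both = backbone[:20] + "CGHC" + backbone[20:50] + signature + backbone[50:]
    assert scan_gilt(with_both).family == "gilt"
    # CXXC alone is not enough
    no_sig = backbone[:20] + "CGHC" + backbone[20:] + backbone
    assert scan_gilt(no_sig).family == "none"
    # one mismatch in the signature tolerated by default
    mutated = with_both.replace("CQHGLAEC", "CQHGLAEA", 1)
    assert scan_gilt(mutated).family == "gilt"
    assert scan_gilt(mutated, max_mismatches=0).family == "none"


def test_glycine_rich_tail_boundary():
    tail_12 = "G" * 12 + "A" * 18  # fraction 0.4, inclusive
    assert scan_glycine_rich("W" * 30 + tail_12).family == "acanthoscurrin_like"
    tail_11 = "G" * 11 + "A" * 19  # fraction ~0.367
    assert scan_glycine_rich("W" * 30 + tail_11).family == "none"
    assert scan_glycine_rich("WADEKRST" * 10).family == "none"


def test_homology_family_call_recognizes_dae2(demo_transcriptome, reference_set):
    _, truth = demo_transcriptome
    families = {rid: rid.replace("ref_", "") for rid in reference_set}
    planted = truth.planted()
    row = planted[planted["family"] == "dae2"].iloc[0]
    ann = homology_family_call(row["protein"], reference_set, families)
    assert ann.family == "dae2"
    # an unrelated random protein stays unassigned
    rng = np.random.default_rng(0)
    junk = "".join(rng.choice(list("ADEFGHIKLMNPQRSTVWY"), 150))
    assert homology_family_call(junk, reference_set, families).family == "none"


# ---------------------------------------------------------------------------
# class abundance
# ---------------------------------------------------------------------------

def _tpm(values: dict, index, conditions):
    df = pd.DataFrame(values, index=index)
    return TpmMatrix(tpm=df, effective_lengths=pd.Series(1.0, index=index),
                     conditions=conditions)


def test_class_abundance_ratios_and_normalization():
    tpm = _tpm({"UF1": [2.7, 50.0, 47.3], "UF2": [2.7, 50.0, 47.3]},
               ["amp", "household", "other"], {"UF1": "UF", "UF2": "UF"})
    classes = {"amp": "Immunity", "household": "Metabolism", "other": "Unknown"}
    pct = class_abundance(tpm, classes)
    assert pct.loc["Immunity", "UF"] == pytest.approx(2.7)
    assert pct["UF"].sum() == pytest.approx(100.0, abs=1e-9)

    solo = _tpm({"UF1": [10.0]}, ["only"], {"UF1": "UF"})
    assert class_abundance(solo, {"only": "Immunity"}).loc["Immunity", "UF"] == 100.0

    even = _tpm({"UF1": [30.0, 30.0]}, ["a", "b"], {"UF1": "UF"})
    pct = class_abundance(even, {"a": "X", "b": "Y"})
    assert pct["UF"].tolist() == pytest.approx([50.0, 50.0])


def test_class_abundance_requires_full_labelling():
    tpm = _tpm({"UF1": [1.0, 2.0]}, ["a", "b"], {"UF1": "UF"})
    with pytest.raises(ValueError):
        class_abundance(tpm, {"a": "X"})
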