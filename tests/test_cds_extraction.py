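"""CDS extraction: ORF discovery, homology, signal peptides, clustering, TPM."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from guardamp.cds_extraction import (
    CountsMatrix,
    HomologyHit,
    compute_tpm,
    consolidate,
    extract_by_homology,
    filter_expressed,
    find_orfs,
    match_homology,
    pairwise_identity,
    select_start,
    signal_peptide_score,
)

# independent six-frame oracle lives in tests/_oracles.py
from _oracles import brute_force_orfs, revcomp

_revcomp = revcomp


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    seq=st.text(alphabet="ACGTN", min_size=0, max_size=2000),
    min_nt=st.sampled_from([30, 90, 175]),
)
def test_orf_finder_matches_six_frame_oracle(seq, min_nt):
    observed = {(o.strand, o.frame, o.start, o.end) for o in find_orfs(seq, min_nt)}
    assert observed == brute_force_orfs(seq, min_nt)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(seq=st.text(alphabet="ACGT", min_size=60, max_size=800))
def test_orf_reverse_complement_symmetry(seq):
    """ORFs of the reverse complement are the strand-flipped, mirrored ORFs."""
    length = len(seq)
    fwd = {(o.strand, o.start, o.end, o.protein) for o in find_orfs(seq, 30)}
    flipped = {
        ("+" if s == "-" else "-", length - e, length - b, p)
        for s, b, e, p in fwd
    }
    rev = {(o.strand, o.start, o.end, o.protein) for o in find_orfs(_revcomp(seq), 30)}
    assert rev == flipped


def test_orf_finder_handcheckable_cases():
    assert find_orfs("N" * 100) == []
    assert find_orfs("") == []
    with pytest.raises(ValueError):
        find_orfs("ACGTU")
    orfs = find_orfs("ATGAAATAA", min_nt=6)
    stopped = [o for o in orfs if o.has_stop]
    assert len(stopped) == 1
    mk = stopped[0]
    assert (mk.protein, mk.start, mk.end, mk.strand) == ("MK", 0, 6, "+")
    assert mk.has_met_start


def test_orf_planted_run_in_frame_plus_two():
    """A 300-nt stop-free run planted in frame +2 is recovered exactly."""
    rng = np.random.default_rng(11)
    # a stop-free codon run: codons drawn from a stop-free codon pool
    safe = ["GCA", "TGC", "AAA", "CTG", "ATG", "CGT"]
    planted = "".join(rng.choice(safe, 100))
    seq = "AA" + "TAA" * 67 + planted + "TAA" + "".join(rng.choice(list("ACGT"), 50))
    start = 2 + 3 * 67
    hits = [
        o for o in find_orfs(seq, 175)
        if (o.strand, o.start, o.end) == ("+", start, start + 300)
    ]
    assert len(hits) == 1
    assert hits[0].has_stop
    # crosscheck the full candidate list with the independent oracle
    observed = {(o.strand, o.frame, o.start, o.end) for o in find_orfs(seq, 175)}
    assert observed == brute_force_orfs(seq, 175)


# ---------------------------------------------------------------------------
# homology
# ---------------------------------------------------------------------------

REF20 = "MKWVCHQDERTLYNAGFSPI"  # 20 distinct residues


def test_homology_self_match_full_coverage():
    hits = match_homology(REF20, {"ref": REF20}, min_score=20)
    assert hits and hits[0].subject_coverage == 1.0 and hits[0].identity == 1.0


def test_homology_half_query_covers_half_subject():
    hits = match_homology(REF20[:10], {"ref": REF20}, min_score=20)
    assert hits and hits[0].subject_coverage == pytest.approx(0.5)


def test_homology_unrelated_protein_no_hit():
    assert match_homology("K" * 30, {"ref": "G" * 30}) == []
    assert match_homology("", {"ref": REF20}) == []
    with pytest.raises(ValueError):
        match_homology(REF20, {})


def _make_orf(protein: str, tid="t1"):
    from guardamp.cds_extraction import OrfCandidate

    return OrfCandidate(
        transcript_id=tid, strand="+", frame=0, start=0, end=3 * len(protein),
        has_met_start=protein.startswith("M"), protein=protein, has_stop=True,
    )


@pytest.mark.parametrize(
    "coverage,expected", [(0.70, 1), (0.699, 0), (0.9, 1)],
    ids=["at-threshold-inclusive", "just-below", "well-above"],
)
def test_extract_by_homology_coverage_boundary(coverage, expected):
    orf = _make_orf("MKWVCHQDERTLYNAGFSPI")
    hit = HomologyHit(
        query_id=orf.orf_id, subject_id="ref", score=100.0,
        subject_coverage=coverage, identity=0.9,
        query_span=(0, 14), subject_span=(0, 14),
    )
    records = extract_by_homology([orf], {orf.orf_id: [hit]})
    assert len(records) == expected
    if records:
        assert records[0].evidence == "homology"


def test_extract_by_homology_multiple_orfs_per_transcript():
    orfs = [_make_orf("MKWVCHQDERTLYNAGFSPI"), _make_orf("WYHCMKDERT" * 2)]
    hits = {
        o.orf_id: [
            HomologyHit(o.orf_id, "ref", 50.0, 0.8, 0.9, (0, 10), (0, 10))
        ]
        for o in orfs
    }
    assert len(extract_by_homology(orfs, hits)) == 2


# ---------------------------------------------------------------------------
# signal peptides and start selection
# ---------------------------------------------------------------------------

def test_signal_peptide_planted_positive():
    # charged n-region, hydrophobic h-region, A-X-A cleavage
    protein = "MKR" + "ST" + "LLIVLFAVLA" + "AQA" + "GDERKTNQSGYWPH" * 3
    call = signal_peptide_score(protein)
    assert call.call and call.score >= 0.8


def test_signal_peptide_acidic_nterm_negative():
    protein = "M" + "E" * 9 + "QNDTSGRKY" * 5
    call = signal_peptide_score(protein)
    assert not call.call


def test_signal_peptide_length_gate():
    with pytest.raises(ValueError):
        signal_peptide_score("M" + "A" * 38)  # 39 residues
    with pytest.raises(ValueError):
        signal_peptide_score("K" + "A" * 50)  # no Met start


def test_select_start_five_prime_most_met():
    orf = _make_orf("GGGMKKKKKKKKMAAA" + "W" * 30)
    cds = select_start(orf)
    assert cds.protein.startswith("MKKK")
    assert cds.start == 9  # 3 codons trimmed
    assert cds.evidence == "signal_peptide"

    first = _make_orf("MKKK" + "W" * 40)
    assert select_start(first).start == 0

    assert select_start(_make_orf("GGGKKK" + "W" * 40)) is None


def test_select_start_reverse_strand_coordinates():
    from guardamp.cds_extraction import OrfCandidate

    orf = OrfCandidate(
        transcript_id="t", strand="-", frame=0, start=30, end=90,
        has_met_start=False, protein="GGM" + "W" * 17, has_stop=True,
    )
    cds = select_start(orf)
    # trimming 2 codons from the 5' end of a minus-strand ORF lowers `end`
    assert (cds.start, cds.end) == (30, 84)


# ---------------------------------------------------------------------------
# consolidation
# ---------------------------------------------------------------------------

def test_consolidate_identical_and_unrelated():
    seqs = {"a": "ACGT" * 30, "b": "ACGT" * 30, "c": "TTTTGGGG" * 15}
    clusters = dict(consolidate(seqs))
    assert sorted(clusters) == ["a", "c"]  # tie broken lexicographically
    assert sorted(clusters["a"]) == ["a", "b"]


def test_consolidate_95_percent_boundary_inclusive():
    base = ("ACGTGATCCA" * 10)  # 100 nt
    flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
    variant = list(base)
    for pos in (50, 55, 60, 65, 70):
        variant[pos] = flip[variant[pos]]
    variant = "".join(variant)
    assert sum(a != b for a, b in zip(base, variant)) == 5
    assert pairwise_identity(base, variant) == pytest.approx(0.95)
    clusters = consolidate({"long": base, "var": variant}, min_identity=0.95)
    assert len(clusters) == 1


def test_consolidate_empty_input_rejected():
    with pytest.raises(ValueError):
        consolidate({})


# ---------------------------------------------------------------------------
# TPM and expression filter
# ---------------------------------------------------------------------------

def _counts(data, conditions):
    return CountsMatrix(counts=pd.DataFrame(data), conditions=conditions)


def test_tpm_normalization_and_rate_weighting():
    cm = _counts({"L1": [10, 90]}, {"L1": "UF"})
    lengths = pd.Series([1000.0, 2000.0], index=cm.counts.index)
    tpm = compute_tpm(cm, lengths)
    assert tpm.tpm["L1"].tolist() == pytest.approx([181818.18, 818181.82], abs=0.01)

    single = compute_tpm(_counts({"L1": [7]}, {"L1": "UF"}),
                         pd.Series([500.0], index=[0]))
    assert single.tpm["L1"].iloc[0] == pytest.approx(1e6)

    equal = compute_tpm(_counts({"L1": [5, 5]}, {"L1": "UF"}),
                        pd.Series([800.0, 800.0], index=[0, 1]))
    assert equal.tpm["L1"].tolist() == pytest.approx([500000.0, 500000.0])


def test_tpm_columns_sum_to_one_million():
    rng = np.random.default_rng(3)
    cm = _counts({f"L{i}": rng.integers(0, 500, 40) for i in range(6)},
                 {f"L{i}": "UF" for i in range(6)})
    tpm = compute_tpm(cm, pd.Series(rng.integers(200, 3000, 40).astype(float)))
    assert np.allclose(tpm.tpm.sum(axis=0), 1e6, rtol=1e-9)


def test_tpm_all_zero_library_warns_not_errors():
    cm = _counts({"L1": [0, 0], "L2": [3, 4]}, {"L1": "UF", "L2": "UF"})
    with pytest.warns(UserWarning, match="all-zero"):
        tpm = compute_tpm(cm, pd.Series([100.0, 100.0]))
    assert (tpm.tpm["L1"] == 0).all()


def test_expression_filter_condition_mean_rule():
    # three UF replicates and one WF replicate per gene
    conditions = {"UF1": "UF", "UF2": "UF", "UF3": "UF", "WF1": "WF"}
    tpm_values = pd.DataFrame(
        {
            "UF1": [4.9, 0.0, 15.0],
            "UF2": [4.9, 0.0, 0.0],
            "UF3": [4.9, 0.0, 0.0],
            "WF1": [5.0, 0.0, 0.0],
        },
        index=["boundary", "silent", "bursty"],
    )
    from guardamp.cds_extraction import TpmMatrix

    tpm = TpmMatrix(tpm=tpm_values, effective_lengths=pd.Series(1.0, index=tpm_values.index),
                    conditions=conditions)
    kept = filter_expressed(tpm, min_avg=5)
    # 'boundary' passes via the WF condition (mean 5.0, inclusive);
    # 'bursty' passes via UF (mean (15+0+0)/3 = 5.0) — a mean rule, not per-replicate
    assert kept == ["boundary", "bursty"]
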