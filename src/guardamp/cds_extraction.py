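"""CDS extraction from an assembled transcriptome.

Coding sequences are recovered by two complementary routes, mirroring how
midgut transcriptomes are typically curated:

* **homology** — every open reading frame of at least 175 nt (a stop-free
  codon run in any of the six frames, stop codon excluded, Met start not
  required) is aligned against a reference protein set with Smith-Waterman
  (BLOSUM62, affine gaps 11/1); an ORF whose best hit covers >= 70% of the
  matched (subject) protein is extracted;
* **signal peptide** — ORFs that start with a methionine and encode at
  least 40 residues are scored with a signal-peptide heuristic; for
  positives the Met codon closest to the 5' end of the frame is chosen as
  the start codon.

Redundant sequences (>= 95% identical) are consolidated by greedy
longest-first clustering, expression is quantified as transcripts per
million (TPM), and CDSs are retained when their mean TPM reaches 5 in at
least one biological condition.

Coordinates are 0-based half-open on the forward strand of the input
transcript, with a strand flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

__all__ = [
    "OrfCandidate",
    "HomologyHit",
    "CdsRecord",
    "CountsMatrix",
    "TpmMatrix",
    "find_orfs",
    "match_homology",
    "extract_by_homology",
    "signal_peptide_score",
    "SignalPeptideCall",
    "select_start",
    "consolidate",
    "compute_tpm",
    "filter_expressed",
]

_NUC = set("ACGTN")
_STOPS = {"TAA", "TAG", "TGA"}

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrfCandidate:
    """A maximal stop-free codon run in one of the six reading frames."""

    transcript_id: str
    strand: str  # '+' or '-'
    frame: int  # 0, 1, 2 on the scanned strand
    start: int  # 0-based, forward-strand coordinates
    end: int  # half-open; (end - start) % 3 == 0, stop codon excluded
    has_met_start: bool
    protein: str
    has_stop: bool  # False when truncated by the transcript end

    @property
    def orf_id(self) -> str:
        return f"{self.transcript_id}|{self.strand}{self.frame}|{self.start}-{self.end}"

    @property
    def length_nt(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    score: float
    subject_coverage: float  # aligned subject residues / subject length
    identity: float  # matches / aligned columns
    query_span: tuple[int, int]
    subject_span: tuple[int, int]


@dataclass(frozen=True)
class CdsRecord:
    cds_id: str
    transcript_id: str
    strand: str
    start: int
    end: int
    protein: str
    evidence: str  # 'homology' | 'signal_peptide'
    source_hit: HomologyHit | None = None


@dataclass
class CountsMatrix:
    """Raw read counts, CDS x library, with per-library condition labels."""

    counts: pd.DataFrame
    conditions: dict[str, str]  # library id -> condition label

    def __post_init__(self) -> None:
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"libraries without a condition label: {sorted(missing)}")

    def libraries_for(self, condition: str) -> list[str]:
        return [lib for lib in self.counts.columns if self.conditions[lib] == condition]

    @property
    def condition_order(self) -> list[str]:
        seen: list[str] = []
        for lib in self.counts.columns:
            c = self.conditions[lib]
            if c not in seen:
                seen.append(c)
        return seen


@dataclass
class TpmMatrix:
    """Transcripts-per-million matrix; every library column sums to 1e6."""

    tpm: pd.DataFrame
    effective_lengths: pd.Series
    conditions: dict[str, str]

    def libraries_for(self, condition: str) -> list[str]:
        return [lib for lib in self.tpm.columns if self.conditions[lib] == condition]

    @property
    def condition_order(self) -> list[str]:
        seen: list[str] = []
        for lib in self.tpm.columns:
            c = self.conditions[lib]
            if c not in seen:
                seen.append(c)
        return seen

    def condition_means(self) -> pd.DataFrame:
        """Per-condition mean TPM across replicate libraries."""
        return pd.DataFrame(
            {c: self.tpm[self.libraries_for(c)].mean(axis=1) for c in self.condition_order}
        )


# ---------------------------------------------------------------------------
# ORF discovery
# ---------------------------------------------------------------------------

def _scan_strand(seq: str, transcript_id: str, strand: str, min_nt: int, length: int):
    """Yield ORFs from one strand; coordinates mapped back to the forward strand."""
    for frame in range(3):
        n_codons = (length - frame) // 3
        boundaries: list[tuple[int, int, bool]] = []  # (run_start, run_end, has_stop)
        run_start = frame
        for ci in range(n_codons):
            i = frame + 3 * ci
            if seq[i : i + 3] in _STOPS:
                boundaries.append((run_start, i, True))
                run_start = i + 3
        boundaries.append((run_start, frame + 3 * n_codons, False))  # truncated tail
        for rs, re, has_stop in boundaries:
            if re - rs < min_nt:
                continue
            protein = str(Seq(seq[rs:re]).translate())
            if strand == "+":
                fstart, fend = rs, re
            else:
                fstart, fend = length - re, length - rs
            yield OrfCandidate(
                transcript_id=transcript_id,
                strand=strand,
                frame=frame,
                start=fstart,
                end=fend,
                has_met_start=protein.startswith("M"),
                protein=protein,
                has_stop=has_stop,
            )


def find_orfs(transcript, min_nt: int = 175, transcript_id: str = "") -> list[OrfCandidate]:
    """All ORFs of at least ``min_nt`` nucleotides across the six frames.

    An ORF is a maximal stop-free codon run ending at a stop codon or at the
    transcript end (truncated ORFs are kept); its length excludes the stop
    codon.  Codons containing N translate to X and never count as stops.
    """
    if min_nt < 3:
        raise ValueError("min_nt must be >= 3")
    if hasattr(transcript, "seq"):  # SeqRecord
        transcript_id = transcript_id or transcript.id
        seq = str(transcript.seq)
    else:
        seq = str(transcript)
    seq = seq.upper()
    if not seq:
        return []
    bad = set(seq) - _NUC
    if bad:
        raise ValueError(f"non-IUPAC nucleotide symbols: {sorted(bad)}")
    length = len(seq)
    rc = str(Seq(seq).reverse_complement())
    orfs = list(_scan_strand(seq, transcript_id, "+", min_nt, length))
    orfs += list(_scan_strand(rc, transcript_id, "-", min_nt, length))
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


# ---------------------------------------------------------------------------
# homology search (Smith-Waterman stand-in for BLAST at desk scale)
# ---------------------------------------------------------------------------

def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def match_homology(
    protein: str,
    reference_proteins: dict[str, str],
    query_id: str = "query",
    min_score: float = 40.0,
    prescreen_k: int = 4,
) -> list[HomologyHit]:
    """Local alignment of a protein against a reference set.

    Smith-Waterman with BLOSUM62 and affine gaps (open 11, extend 1),
    preceded by a shared-k-mer prescreen.  ``subject_coverage`` is the
    fraction of the subject protein covered by the alignment, matching the
    "coverage ... for a matching protein" extraction rule.  Hits are sorted
    by score, descending.
    """
    if not reference_proteins:
        raise ValueError("empty reference protein set")
    protein = protein.upper().rstrip("*")
    if not protein:
        return []
    aligner = _protein_aligner()
    qkmers = _kmer_set(protein, prescreen_k)
    hits: list[HomologyHit] = []
    for sid, subject in reference_proteins.items():
        subject = subject.upper().rstrip("*")
        if not subject:
            continue
        if len(protein) >= prescreen_k and len(subject) >= prescreen_k:
            if not (qkmers & _kmer_set(subject, prescreen_k)):
                continue
        alns = aligner.align(protein, subject)
        if len(alns) == 0:
            continue
        aln = alns[0]
        if aln.score < min_score:
            continue
        qblocks, sblocks = aln.aligned
        matches = 0
        columns = 0
        s_covered = 0
        for (qs, qe), (ss, se) in zip(qblocks, sblocks):
            matches += sum(1 for a, b in zip(protein[qs:qe], subject[ss:se]) if a == b)
            columns += qe - qs
            s_covered += se - ss
        # gap columns between aligned blocks count toward alignment length
        if len(qblocks):
            q_span = (int(qblocks[0][0]), int(qblocks[-1][1]))
            s_span = (int(sblocks[0][0]), int(sblocks[-1][1]))
            columns += (q_span[1] - q_span[0] - columns) + (s_span[1] - s_span[0] - s_covered)
        else:  # pragma: no cover - empty alignment
            continue
        hits.append(
            HomologyHit(
                query_id=query_id,
                subject_id=sid,
                score=float(aln.score),
                subject_coverage=s_covered / len(subject),
                identity=matches / columns if columns else 0.0,
                query_span=q_span,
                subject_span=s_span,
            )
        )
    hits.sort(key=lambda h: (-h.score, h.subject_id))
    return hits


def extract_by_homology(
    orfs: list[OrfCandidate],
    hits: dict[str, list[HomologyHit]],
    min_coverage: float = 0.70,
) -> list[CdsRecord]:
    """Emit a CDS for every ORF whose best hit covers enough of its subject.

    ``hits`` maps ``OrfCandidate.orf_id`` to that ORF's homology hits; the
    coverage threshold is inclusive (exactly 70% qualifies).
    """
    records: list[CdsRecord] = []
    for orf in orfs:
        orf_hits = hits.get(orf.orf_id, [])
        if not orf_hits:
            continue
        best = max(orf_hits, key=lambda h: h.score)
        if best.subject_coverage >= min_coverage:
            records.append(
                CdsRecord(
                    cds_id=f"{orf.orf_id}|hom",
                    transcript_id=orf.transcript_id,
                    strand=orf.strand,
                    start=orf.start,
                    end=orf.end,
                    protein=orf.protein,
                    evidence="homology",
                    source_hit=best,
                )
            )
    return records


# ---------------------------------------------------------------------------
# signal-peptide heuristic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignalPeptideCall:
    score: float
    call: bool
    charge_component: float
    hydrophobicity_component: float
    cleavage_component: float
    cleavage_site: int | None  # 1-based last residue of the signal peptide


def signal_peptide_score(protein: str, threshold: float = 0.8) -> SignalPeptideCall:
    """Heuristic secretion-signal score in [0, 1].

    Weighted sum of three classic signal-peptide features: net positive
    charge of the n-region (residues 1-5), the best 8-residue Kyte-
    Doolittle hydrophobicity window in the h-region (residues 6-20), and a
    small-residue (A/G/S/C) match at the -3/-1 positions of a cleavage site
    scanned over residues 15-30.  This is a deliberately simple, documented
    stand-in for a trained signal-peptide predictor; the pipeline contract
    is the boolean gate, not the score.
    """
    protein = protein.upper().rstrip("*")
    if len(protein) < 40:
        raise ValueError("signal-peptide scoring requires >= 40 residues")
    if not protein.startswith("M"):
        raise ValueError("signal-peptide scoring requires a Met start")

    n_region = protein[:5]
    net = sum(aa in "KR" for aa in n_region) - sum(aa in "DE" for aa in n_region)
    charge = min(max((net + 1) / 3.0, 0.0), 1.0)

    h_region = protein[5:20]
    window = 8
    best = max(
        np.mean([KYTE_DOOLITTLE.get(aa, 0.0) for aa in h_region[i : i + window]])
        for i in range(len(h_region) - window + 1)
    )
    hydro = min(max((best - 0.5) / 2.5, 0.0), 1.0)

    small = set("AGSC")
    cleave = 0.0
    site = None
    for p in range(15, 31):  # cleavage after residue p (1-based)
        m1 = protein[p - 1] in small
        m3 = protein[p - 3] in small
        c = (0.5 * m1) + (0.5 * m3)
        if c > cleave:
            cleave = c
            site = p
    score = 0.25 * charge + 0.45 * hydro + 0.30 * cleave
    return SignalPeptideCall(
        score=score,
        call=score >= threshold,
        charge_component=charge,
        hydrophobicity_component=hydro,
        cleavage_component=cleave,
        cleavage_site=site,
    )


def select_start(orf: OrfCandidate) -> CdsRecord | None:
    """Trim an ORF to start at its 5'-most methionine.

    Returns a signal-peptide-evidence CDS, or None when the ORF encodes no
    methionine at all.
    """
    idx = orf.protein.find("M")
    if idx < 0:
        return None
    if orf.strand == "+":
        start, end = orf.start + 3 * idx, orf.end
    else:
        start, end = orf.start, orf.end - 3 * idx
    return CdsRecord(
        cds_id=f"{orf.orf_id}|sig",
        transcript_id=orf.transcript_id,
        strand=orf.strand,
        start=start,
        end=end,
        protein=orf.protein[idx:],
        evidence="signal_peptide",
    )


# ---------------------------------------------------------------------------
# redundancy consolidation (greedy clustering, CD-HIT style)
# ---------------------------------------------------------------------------

def _identity_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(a: str, b: str, aligner: PairwiseAligner | None = None) -> float:
    """Matches / alignment length from a global alignment of the pair."""
    if not a or not b:
        return 0.0
    aligner = aligner or _identity_aligner()
    aln = aligner.align(a, b)[0]
    ablocks, bblocks = aln.aligned
    matches = sum(
        1
        for (as_, ae), (bs, be) in zip(ablocks, bblocks)
        for x, y in zip(a[as_:ae], b[bs:be])
        if x == y
    )
    aligned_a = sum(ae - as_ for as_, ae in ablocks)
    aligned_b = sum(be - bs for bs, be in bblocks)
    # global alignment length = aligned columns + gap columns on either side
    length = aligned_a + (len(a) - aligned_a) + (len(b) - aligned_b)
    return matches / length if length else 0.0


def consolidate(
    sequences: dict[str, str], min_identity: float = 0.95
) -> list[tuple[str, list[str]]]:
    """Greedy longest-first clustering at an identity threshold (inclusive).

    Returns ``(representative_id, member_ids)`` per cluster; every member is
    at least ``min_identity`` identical to its representative.  Ties in
    length break lexicographically by id, so the outcome is deterministic.
    """
    if not sequences:
        raise ValueError("no sequences to consolidate")
    order = sorted(sequences, key=lambda k: (-len(sequences[k]), k))
    aligner = _identity_aligner()
    reps: list[str] = []
    clusters: dict[str, list[str]] = {}
    for sid in order:
        seq = sequences[sid]
        placed = False
        for rep in reps:
            rep_seq = sequences[rep]
            # identity cannot exceed shorter/longer: skip hopeless pairs
            if len(seq) < min_identity * len(rep_seq):
                continue
            if pairwise_identity(seq, rep_seq, aligner) >= min_identity:
                clusters[rep].append(sid)
                placed = True
                break
        if not placed:
            reps.append(sid)
            clusters[sid] = [sid]
    return [(rep, clusters[rep]) for rep in reps]


# ---------------------------------------------------------------------------
# quantification and expression filtering
# ---------------------------------------------------------------------------

def compute_tpm(counts: CountsMatrix, effective_lengths: pd.Series) -> TpmMatrix:
    """Transcripts per million: TPM_i = 1e6 * (c_i/l_i) / sum_j (c_j/l_j)."""
    lengths = effective_lengths.reindex(counts.counts.index)
    if lengths.isna().any():
        raise ValueError("effective length missing for some CDSs")
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    if (counts.counts.values < 0).any():
        raise ValueError("negative counts")
    rate = counts.counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    zero_libs = totals[totals == 0].index.tolist()
    if zero_libs:
        warnings.warn(f"all-zero libraries: {zero_libs}", stacklevel=2)
        totals = totals.replace(0, np.nan)
    tpm = rate.div(totals, axis=1).fillna(0.0) * 1e6
    return TpmMatrix(tpm=tpm, effective_lengths=lengths, conditions=dict(counts.conditions))


def filter_expressed(tpm: TpmMatrix, min_avg: float = 5.0) -> list[str]:
    """CDS ids whose mean TPM reaches ``min_avg`` in >= 1 condition (inclusive)."""
    means = tpm.condition_means()
    keep = means.max(axis=1) >= min_avg
    return [str(i) for i in means.index[keep]]
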