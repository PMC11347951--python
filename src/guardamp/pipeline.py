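"""End-to-end pipeline driver: simulate -> extract -> quantify -> annotate -> DE.

Reproduces the analysis flow of a guard-AMP discovery study on synthetic
inputs: generate a transcript pool and count matrix, extract CDSs by
homology and signal-peptide evidence, consolidate redundancy, quantify TPM,
filter on expression, annotate AMP families and functional classes, and
call differential expression for the fed-versus-unfed and
bacteria-versus-water contrasts.  Every stage writes a plain-text artifact
and the report summarizes the counts a reader would put in a results table.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as gio
from .annotation import (
    DEFAULT_VOCABULARY,
    annotate_protein,
    class_abundance,
    classify_by_vocabulary,
)
from .cds_extraction import (
    CdsRecord,
    CountsMatrix,
    TpmMatrix,
    compute_tpm,
    consolidate,
    extract_by_homology,
    filter_expressed,
    find_orfs,
    match_homology,
    select_start,
    signal_peptide_score,
)
from .expression_stats import de_test, summarize_replicates
from .synthetic_data import (
    CountsSimConfig,
    TranscriptomeSimConfig,
    TruthTable,
    family_label,
    generate_counts,
    generate_transcriptome,
    reference_proteins,
)

logger = logging.getLogger("guardamp")

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "extract_cds_records"]

# descriptions attached to the synthetic reference proteins, consumed by the
# vocabulary classifier exactly as BLAST hit descriptions would be
REFERENCE_DESCRIPTIONS = {
    "ref_defensin_CVMK": "putative defensin precursor",
    "ref_defensin_TyrC": "defensin, midgut isoform",
    "ref_microplusin_type1": "microplusin/ricinusin antimicrobial peptide",
    "ref_microplusin_type2": "microplusin, histidine-rich type 2",
    "ref_dae2": "domesticated amidase effector dae2",
    "ref_lysozyme_c": "c-type lysozyme",
    "ref_gilt": "gamma-interferon-inducible lysosomal thiol reductase gilt",
    "ref_acanthoscurrin_like": "acanthoscurrin-like glycine-rich protein",
}

REFERENCE_FAMILIES = {
    "ref_defensin_CVMK": "defensin",
    "ref_defensin_TyrC": "defensin",
    "ref_microplusin_type1": "microplusin_type1",
    "ref_microplusin_type2": "microplusin_type2",
    "ref_dae2": "dae2",
    "ref_lysozyme_c": "lysozyme_c",
    "ref_gilt": "gilt",
    "ref_acanthoscurrin_like": "acanthoscurrin_like",
}


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters; defaults are the study's printed thresholds."""

    seed: int = 0
    outdir: str = "guardamp_run"
    # simulation
    n_decoys: int = 40
    library_size: int = 1_000_000
    nb_dispersion: float = 0.05
    fraction_fed_modulated: float = 0.3
    fed_logfc_magnitude: float = 2.0
    bacteria_logfc_magnitude: float = 0.0
    # extraction
    min_orf_nt: int = 175
    min_coverage: float = 0.70
    min_identity: float = 0.95
    require_met: bool = False
    signal_threshold: float = 0.8
    # quantification / DE
    min_avg_tpm: float = 5.0
    lfc_cut: float = 1.0
    fdr_cut: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.fdr_cut <= 1:
            raise ValueError("fdr_cut must lie in (0, 1]")
        if not 0 < self.min_coverage <= 1 or not 0 < self.min_identity <= 1:
            raise ValueError("coverage/identity thresholds must lie in (0, 1]")
        if self.min_orf_nt < 3 or self.min_avg_tpm < 0 or self.lfc_cut < 0:
            raise ValueError("invalid threshold configuration")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineReport:
    n_transcripts: int
    n_orfs: int
    n_cds_extracted: int
    n_cds_homology: int
    n_cds_signal: int
    n_clusters: int
    n_retained: int
    n_modulated: dict[str, int]
    amp_families: dict[str, str]
    functional_classes: dict[str, str]
    class_percent_uf: dict[str, float]
    replicate_summaries: dict[str, tuple[float, float]]
    planted_recovered: int
    planted_total: int


def extract_cds_records(
    transcripts,
    references: dict[str, str],
    min_orf_nt: int = 175,
    min_coverage: float = 0.70,
    signal_threshold: float = 0.8,
    require_met: bool = False,
):
    """Run both extraction routes over a transcript set.

    Returns (records, n_orfs, signal_calls) where ``signal_calls`` maps the
    cds_id of each signal-peptide CDS to its scoring result (the cleavage
    site locates the mature peptide for downstream motif scans).
    """
    all_records: list[CdsRecord] = []
    signal_calls = {}
    n_orfs = 0
    for rec in transcripts:
        orfs = find_orfs(rec, min_nt=min_orf_nt)
        if require_met:
            orfs = [o for o in orfs if o.has_met_start]
        n_orfs += len(orfs)
        hits = {
            o.orf_id: match_homology(o.protein, references, query_id=o.orf_id)
            for o in orfs
        }
        homology_records = extract_by_homology(orfs, hits, min_coverage=min_coverage)
        claimed = {r.transcript_id for r in homology_records}
        all_records.extend(homology_records)
        # signal-peptide route: 5'-most Met, >= 40 aa, heuristic gate
        for orf in orfs:
            if orf.transcript_id in claimed:
                continue
            cds = select_start(orf)
            if cds is None or len(cds.protein) < 40:
                continue
            call = signal_peptide_score(cds.protein, threshold=signal_threshold)
            if call.call:
                all_records.append(cds)
                signal_calls[cds.cds_id] = call
    return all_records, n_orfs, signal_calls


def _infer_mature(protein: str, call=None) -> str | None:
    """Locate the mature peptide behind the signal/pro region.

    Uses the recorded signal-peptide cleavage site when the CDS came from
    the signal route; homology-route CDSs are trimmed to their first Met
    and the cleavage scan is applied to the trimmed protein.
    """
    if call is not None and call.cleavage_site:
        return protein[call.cleavage_site :]
    idx = protein.find("M")
    if idx < 0:
        return None
    trimmed = protein[idx:]
    if len(trimmed) < 40:
        return None
    scored = signal_peptide_score(trimmed, threshold=0.0)
    if scored.cleavage_site:
        return trimmed[scored.cleavage_site :]
    return None


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full synthetic study flow and write all artifacts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    def stage(name: str, **params) -> None:
        logger.info("stage=%s seed=%d params=%s", name, config.seed,
                     json.dumps(params, sort_keys=True, default=str))

    try:
        # --- simulate ------------------------------------------------------
        sim_cfg = TranscriptomeSimConfig(n_decoys=config.n_decoys, seed=config.seed)
        stage("simulate-transcriptome", n_decoys=config.n_decoys)
        transcripts, truth = generate_transcriptome(sim_cfg)
        gio.write_fasta(transcripts, outdir / "transcripts.fasta")

        counts_cfg = CountsSimConfig(
            library_size=config.library_size,
            nb_dispersion=config.nb_dispersion,
            fraction_fed_modulated=config.fraction_fed_modulated,
            fed_logfc_magnitude=config.fed_logfc_magnitude,
            bacteria_logfc_magnitude=config.bacteria_logfc_magnitude,
            seed=config.seed + 1,
        )
        stage("simulate-counts", library_size=config.library_size)
        lengths = {r.id: len(r.seq) for r in transcripts}
        counts, truth = generate_counts(truth, counts_cfg, transcript_lengths=lengths)
        gio.write_counts(counts, outdir / "counts.tsv")
        truth.table.to_csv(outdir / "truth.tsv", sep="\t")

        # --- extract CDSs --------------------------------------------------
        references = reference_proteins()
        stage("extract-cds", min_orf_nt=config.min_orf_nt,
              min_coverage=config.min_coverage)
        records, n_orfs, signal_calls = extract_cds_records(
            transcripts,
            references,
            min_orf_nt=config.min_orf_nt,
            min_coverage=config.min_coverage,
            signal_threshold=config.signal_threshold,
            require_met=config.require_met,
        )
        gio.write_fasta(
            sorted(((r.cds_id, r.protein) for r in records)),
            outdir / "cds_proteins.fasta",
        )

        # --- consolidate ---------------------------------------------------
        stage("consolidate", min_identity=config.min_identity)
        by_id = {r.cds_id: r for r in records}
        clusters = consolidate(
            {r.cds_id: r.protein for r in records}, min_identity=config.min_identity
        )
        representatives = [by_id[rep] for rep, _ in clusters]

        # --- quantify ------------------------------------------------------
        stage("quantify", min_avg_tpm=config.min_avg_tpm)
        # one representative CDS per transcript inherits that transcript's counts
        rep_by_transcript: dict[str, CdsRecord] = {}
        for r in representatives:
            cur = rep_by_transcript.get(r.transcript_id)
            if cur is None or len(r.protein) > len(cur.protein):
                rep_by_transcript[r.transcript_id] = r
        cds_counts = counts.counts.loc[list(rep_by_transcript)]
        cds_counts.index = [rep_by_transcript[t].cds_id for t in rep_by_transcript]
        cds_matrix = CountsMatrix(counts=cds_counts, conditions=counts.conditions)
        eff_lengths = pd.Series(
            {r.cds_id: float(r.end - r.start) for r in rep_by_transcript.values()}
        )
        tpm = compute_tpm(cds_matrix, eff_lengths)
        retained = filter_expressed(tpm, min_avg=config.min_avg_tpm)
        gio.write_tpm(tpm, outdir / "tpm.tsv")

        # --- annotate ------------------------------------------------------
        stage("annotate", n_retained=len(retained))
        amp_families: dict[str, str] = {}
        functional_classes: dict[str, str] = {}
        for cds_id in sorted(retained):
            rec = by_id[cds_id]
            mature = _infer_mature(rec.protein, signal_calls.get(cds_id))
            ann = annotate_protein(
                rec.protein,
                cds_id=cds_id,
                mature_protein=mature,
                homology_references=references,
                homology_families=REFERENCE_FAMILIES,
            )
            amp_families[cds_id] = ann.family
            hits = match_homology(rec.protein, references, query_id=cds_id)
            descriptions = [REFERENCE_DESCRIPTIONS[h.subject_id] for h in hits]
            functional_classes[cds_id] = classify_by_vocabulary(
                descriptions, DEFAULT_VOCABULARY
            )
        pd.DataFrame(
            {
                "cds_id": sorted(retained),
                "functional_class": [functional_classes[c] for c in sorted(retained)],
                "amp_family": [amp_families[c] for c in sorted(retained)],
            }
        ).to_csv(outdir / "annotation.tsv", sep="\t", index=False)

        retained_tpm = TpmMatrix(
            tpm=tpm.tpm.loc[retained],
            effective_lengths=tpm.effective_lengths.loc[retained],
            conditions=tpm.conditions,
        )
        pct = class_abundance(retained_tpm, functional_classes)
        pct.round(4).to_csv(outdir / "class_abundance.tsv", sep="\t")

        # --- differential expression ---------------------------------------
        n_modulated: dict[str, int] = {}
        for name, (a, b) in {
            "WF_vs_UF": ("UF", "WF"),
            "Mic_vs_WF": ("WF", "Mic"),
            "Pan_vs_WF": ("WF", "Pan"),
        }.items():
            stage("de", contrast=name, lfc=config.lfc_cut, fdr=config.fdr_cut)
            sub = CountsMatrix(
                counts=cds_matrix.counts.loc[retained], conditions=cds_matrix.conditions
            )
            results = de_test(sub, a, b, lfc_cut=config.lfc_cut, fdr_cut=config.fdr_cut)
            gio.write_de_results(results, outdir / f"de_{name}.tsv")
            n_modulated[name] = sum(r.modulated != "none" for r in results)

        # --- replicate summaries (results-table style) ----------------------
        uf_libs = retained_tpm.libraries_for("UF")
        summaries = {}
        for cds_id in sorted(retained):
            if amp_families[cds_id] != "none":
                mean, sd = summarize_replicates(
                    retained_tpm.tpm.loc[cds_id, uf_libs], ndigits=2
                )
                summaries[cds_id] = (mean, sd)
        pd.DataFrame(
            [(k, v[0], v[1]) for k, v in sorted(summaries.items())],
            columns=["cds_id", "uf_mean_tpm", "uf_sd_tpm"],
        ).to_csv(outdir / "amp_summary.tsv", sep="\t", index=False)

        # --- recovery against the truth table -------------------------------
        planted = truth.planted()
        recovered = 0
        extracted_transcripts = {r.transcript_id for r in records}
        for tid in planted.index:
            if tid in extracted_transcripts:
                recovered += 1

        report = PipelineReport(
            n_transcripts=len(transcripts),
            n_orfs=n_orfs,
            n_cds_extracted=len(records),
            n_cds_homology=sum(r.evidence == "homology" for r in records),
            n_cds_signal=sum(r.evidence == "signal_peptide" for r in records),
            n_clusters=len(clusters),
            n_retained=len(retained),
            n_modulated=n_modulated,
            amp_families=amp_families,
            functional_classes=functional_classes,
            class_percent_uf={k: round(float(v), 4) for k, v in pct["UF"].items()},
            replicate_summaries=summaries,
            planted_recovered=recovered,
            planted_total=len(planted),
        )
        with open(outdir / "report.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    k: v
                    for k, v in dataclasses.asdict(report).items()
                    if k not in ("amp_families", "functional_classes")
                },
                fh,
                sort_keys=True,
            )
        return report
    except Exception as exc:
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
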