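"""Readers and writers for the pipeline's plain-text artifacts.

FASTA via Biopython; counts/TPM/plate/DE tables as TSV with a YAML sidecar
for the library -> condition map.  Writers sort deterministically and fix
float formatting so reruns with the same seed produce identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cds_extraction import CountsMatrix, TpmMatrix
from .expression_stats import DeResult
from .mic_assay import PlateAssay, Well

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_counts",
    "write_counts",
    "read_tpm",
    "write_tpm",
    "read_plate",
    "write_plate",
    "write_de_results",
    "read_de_results",
]


def write_fasta(records, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, tuple):
                rec = SeqRecord(Seq(rec[1]), id=rec[0], description="")
            SeqIO.write(rec, fh, "fasta")


def read_fasta(path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fasta"))


def write_counts(counts: CountsMatrix, path, conditions_path=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    counts.counts.to_csv(path, sep="\t", index_label="cds_id")
    sidecar = Path(conditions_path) if conditions_path else path.with_suffix(".conditions.yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump({"conditions": dict(counts.conditions)}, fh, sort_keys=True)


def read_counts(path, conditions_path=None) -> CountsMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col="cds_id")
    sidecar = Path(conditions_path) if conditions_path else path.with_suffix(".conditions.yaml")
    with open(sidecar) as fh:
        conditions = yaml.safe_load(fh)["conditions"]
    return CountsMatrix(counts=df, conditions=conditions)


def write_tpm(tpm: TpmMatrix, path, conditions_path=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = tpm.tpm.copy()
    out.insert(0, "effective_length", tpm.effective_lengths)
    out.to_csv(path, sep="\t", index_label="cds_id", float_format="%.6f")
    sidecar = Path(conditions_path) if conditions_path else path.with_suffix(".conditions.yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump({"conditions": dict(tpm.conditions)}, fh, sort_keys=True)


def read_tpm(path, conditions_path=None) -> TpmMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col="cds_id")
    lengths = df.pop("effective_length")
    sidecar = Path(conditions_path) if conditions_path else path.with_suffix(".conditions.yaml")
    with open(sidecar) as fh:
        conditions = yaml.safe_load(fh)["conditions"]
    return TpmMatrix(tpm=df, effective_lengths=lengths, conditions=conditions)


def write_plate(plate: PlateAssay, path) -> None:
    """Plate TSV: one row per well (concentration, role, then timepoints)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [f"t_{t:.6f}" for t in plate.times]
    rows = []
    for w in plate.wells:
        rows.append([w.concentration, w.role] + list(w.od))
    df = pd.DataFrame(rows, columns=["concentration", "role"] + cols)
    df.to_csv(path, sep="\t", index_label="well", float_format="%.8g")


def read_plate(path) -> PlateAssay:
    df = pd.read_csv(path, sep="\t", index_col="well")
    tcols = [c for c in df.columns if c.startswith("t_")]
    times = np.array([float(c[2:]) for c in tcols])
    wells = [
        Well(concentration=float(r["concentration"]), role=str(r["role"]),
             od=r[tcols].to_numpy(dtype=float))
        for _, r in df.iterrows()
    ]
    return PlateAssay(times=times, wells=wells)


def write_de_results(results: list[DeResult], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        [
            (r.cds_id, r.log2_fold_change, r.p_value, r.fdr, r.modulated)
            for r in results
        ],
        columns=["cds_id", "log2_fold_change", "p_value", "fdr", "modulated"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_de_results(path) -> list[DeResult]:
    df = pd.read_csv(path, sep="\t")
    return [
        DeResult(
            cds_id=str(r.cds_id),
            log2_fold_change=float(r.log2_fold_change),
            p_value=float(r.p_value),
            fdr=float(r.fdr),
            modulated=str(r.modulated),
        )
        for r in df.itertuples()
    ]
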