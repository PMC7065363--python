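"""Readers and writers for the pipeline's tabular and sequence formats.

All tables are tab-delimited UTF-8 with '.' decimals (taxon names contain
commas); sequences are plain or aligned FASTA via Biopython.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .primers import AlignmentMatrix
from .quant import GeneHitTable
from .simulate import SimulatedExperiment, TruthTable

__all__ = [
    "read_abundance_table",
    "write_abundance_table",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_fraction_metadata",
    "read_truth_table",
    "write_truth_table",
    "read_alignment_fasta",
    "write_alignment_fasta",
    "read_templates_fasta",
    "read_gene_hits",
    "write_gene_hits",
    "write_experiment",
]

ISOTOPE_VOCAB = {"13C", "12C"}
FRACTION_VOCAB = {"heavy", "light"}


def read_abundance_table(path: str | Path, relative: bool = True) -> pd.DataFrame:
    """Taxa x samples matrix from TSV (first column taxon ids, header row
    sample ids).  Blank cells become 0; duplicate taxa and non-numeric cells
    are errors naming the offender."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a taxon-id column plus sample columns")
    taxon_col = df.columns[0]
    taxa = df[taxon_col]
    dups = taxa[taxa.duplicated()].unique()
    if len(dups):
        raise ValueError(f"{path}: duplicate taxon id(s): {list(dups)}")
    data = df.drop(columns=[taxon_col]).replace({"": np.nan})
    numeric = data.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & data.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise ValueError(
            f"{path}: non-numeric value {data.iloc[r, c]!r} at taxon "
            f"{taxa.iloc[r]!r}, sample {data.columns[c]!r}"
        )
    numeric = numeric.fillna(0.0)
    numeric.index = pd.Index(taxa, name="taxon_id")
    if relative:
        vals = numeric.values
        if (vals < 0).any() or (vals > 1).any():
            r, c = np.argwhere((vals < 0) | (vals > 1))[0]
            raise ValueError(
                f"{path}: value {vals[r, c]} at taxon {numeric.index[r]!r}, "
                f"sample {numeric.columns[c]!r} is not a relative abundance"
            )
    return numeric


def write_abundance_table(abundance: pd.DataFrame, path: str | Path) -> None:
    abundance.to_csv(path, sep="\t", index_label="taxon_id")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet TSV with columns sample_id, treatment, isotope,
    fraction_class, replicate and optionally timepoint."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "treatment", "isotope", "fraction_class", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {sorted(missing)}")
    dups = df["sample_id"][df["sample_id"].duplicated()].unique()
    if len(dups):
        raise ValueError(f"{path}: duplicate sample id(s): {list(dups)}")
    bad_iso = set(df["isotope"]) - ISOTOPE_VOCAB
    if bad_iso:
        raise ValueError(f"{path}: isotope must be one of {sorted(ISOTOPE_VOCAB)}, got {sorted(bad_iso)}")
    bad_frac = set(df["fraction_class"]) - FRACTION_VOCAB
    if bad_frac:
        raise ValueError(
            f"{path}: fraction_class must be one of {sorted(FRACTION_VOCAB)}, got {sorted(bad_frac)}"
        )
    if "timepoint" not in df.columns:
        df["timepoint"] = "T1"
    return df


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_fraction_metadata(path: str | Path) -> pd.DataFrame:
    """Gradient-fraction metadata TSV: sample_id, gradient_id, fraction_index,
    refractive_index."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "gradient_id", "fraction_index", "refractive_index"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: fraction metadata missing columns {sorted(missing)}")
    return df


def read_truth_table(path: str | Path) -> TruthTable:
    df = pd.read_csv(path, sep="\t", dtype={"taxon_id": str, "status": str})
    if not {"taxon_id", "status"} <= set(df.columns):
        raise ValueError(f"{path}: truth table needs taxon_id and status columns")
    high_gc: frozenset[str] = frozenset()
    if "high_gc" in df.columns:
        flags = df["high_gc"].astype(str).str.lower().isin({"true", "1"})
        high_gc = frozenset(df.loc[flags, "taxon_id"])
    return TruthTable(
        status=dict(zip(df["taxon_id"], df["status"])), high_gc=high_gc
    )


def write_truth_table(truth: TruthTable, path: str | Path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)


def read_alignment_fasta(path: str | Path) -> AlignmentMatrix:
    return AlignmentMatrix.from_records(SeqIO.parse(str(path), "fasta"))


def write_alignment_fasta(alignment: AlignmentMatrix, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(alignment.row(i)), id=alignment.ids[i], description="")
        for i in range(alignment.n_seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_templates_fasta(path: str | Path) -> dict[str, str]:
    """Plain DNA templates for in-silico PCR, keyed by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_gene_hits(
    path: str | Path, mode: str = "unassembled", total_reads: int | None = None
) -> GeneHitTable:
    """Gene-hit TSV with columns clade, length_bp, hits."""
    df = pd.read_csv(path, sep="\t")
    required = {"clade", "length_bp", "hits"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: gene-hit table missing columns {sorted(missing)}")
    return GeneHitTable(
        clades=tuple(df["clade"].astype(str)),
        lengths_bp=tuple(df["length_bp"].astype(float)),
        hits=tuple(df["hits"].astype(float)),
        mode=mode,
        total_reads=total_reads,
    )


def write_gene_hits(table: GeneHitTable, path: str | Path) -> None:
    pd.DataFrame(
        {"clade": table.clades, "length_bp": table.lengths_bp, "hits": table.hits}
    ).to_csv(path, sep="\t", index=False)


def write_experiment(
    experiment: SimulatedExperiment, truth: TruthTable, outdir: str | Path
) -> dict[str, Path]:
    """Write a simulated experiment as abundance + sample-sheet + truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": outdir / "abundance.tsv",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_abundance_table(experiment.abundance, paths["abundance"])
    write_sample_sheet(experiment.samples, paths["samples"])
    write_truth_table(truth, paths["truth"])
    return paths
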