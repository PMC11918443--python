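"""Readers and writers for every format the pipeline touches.

Expression tables are TSV with genes in rows and a header row of sample ids.
Genomic intervals use the BED convention (0-based, half-open) throughout;
chromosome names pass through verbatim.  Assignments and networks are
exported as TSV/JSON; configuration files are YAML.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .epigenome import IntervalSet, PeakTrack
from .stats_core import STAGES

__all__ = [
    "ExpressionCohort",
    "read_expression_table",
    "write_expression_table",
    "read_stage_table",
    "read_annotation",
    "read_chrom_lengths",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "load_config",
    "save_json",
]

TPM_SCALE = 1e6


@dataclass
class ExpressionCohort:
    """Counts and TPM matrices (genes x samples) with per-sample stage labels."""

    counts: pd.DataFrame
    tpm: pd.DataFrame
    stage: pd.Series

    def __post_init__(self):
        if not self.counts.index.equals(self.tpm.index) or \
           not self.counts.columns.equals(self.tpm.columns):
            raise ValueError("counts and TPM must share gene and sample ids")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if (self.counts.to_numpy() < 0).any() or (self.tpm.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = set(self.counts.columns) - set(self.stage.index)
        if missing:
            raise ValueError(f"samples without stage labels: {sorted(missing)[:5]}")
        bad = set(self.stage.unique()) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")
        self.stage = self.stage.loc[self.counts.columns]

    @classmethod
    def from_counts(cls, counts: pd.DataFrame, stage: pd.Series,
                    gene_lengths=None) -> "ExpressionCohort":
        """Derive TPM from counts by per-sample scaling to 1e6.

        With no gene lengths supplied all genes are treated as equal length,
        so TPM reduces to counts-per-million.
        """
        mat = counts.to_numpy(dtype=float)
        if gene_lengths is not None:
            mat = mat / np.asarray(gene_lengths, dtype=float)[:, None]
        tpm = mat / mat.sum(axis=0, keepdims=True) * TPM_SCALE
        return cls(counts=counts,
                   tpm=pd.DataFrame(tpm, index=counts.index, columns=counts.columns),
                   stage=stage)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def samples_of(self, stage) -> list:
        stages = [stage] if isinstance(stage, str) else list(stage)
        return [s for s in self.sample_ids if self.stage[s] in stages]

    def cpm(self) -> pd.DataFrame:
        """Counts per million (library-size normalised counts)."""
        mat = self.counts.to_numpy(dtype=float)
        return pd.DataFrame(mat / mat.sum(axis=0, keepdims=True) * TPM_SCALE,
                            index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes) -> "ExpressionCohort":
        return ExpressionCohort(counts=self.counts.loc[genes],
                                tpm=self.tpm.loc[genes], stage=self.stage)


def read_expression_table(path, kind: str) -> pd.DataFrame:
    """Read a genes x samples TSV; ``kind`` is 'tpm' or 'counts'."""
    if kind not in ("tpm", "counts"):
        raise ValueError("kind must be 'tpm' or 'counts'")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r}")
    if raw.columns.duplicated().any():
        raise ValueError("duplicate sample ids in header")
    out = {}
    for col in raw.columns:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.index[vals.isna() & raw[col].notna()]
        if len(bad):
            raise ValueError(f"malformed numeric cell at gene {bad[0]!r}, sample {col!r}")
        if vals.isna().any():
            raise ValueError(f"missing value in sample {col!r}")
        out[col] = vals
    df = pd.DataFrame(out, index=raw.index)
    if (df.to_numpy() < 0).any():
        raise ValueError("negative expression value")
    if kind == "counts":
        mat = df.to_numpy()
        if not np.array_equal(mat, np.floor(mat)):
            g, s = np.argwhere(mat != np.floor(mat))[0]
            raise ValueError(
                f"non-integer count at gene {df.index[g]!r}, sample {df.columns[s]!r}")
        df = df.astype(np.int64)
    return df


def write_expression_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_stage_table(path) -> pd.Series:
    """Two-column TSV: sample_id, stage (NCI/MCI/AD)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.lower() for c in df.columns]
    s = pd.Series(df["stage"].to_numpy(), index=df[df.columns[0]], name="stage")
    bad = set(s.unique()) - set(STAGES)
    if bad:
        raise ValueError(f"unknown stage labels: {sorted(bad)}")
    return s


def read_annotation(path) -> pd.DataFrame:
    """Four-column TSV: gene_id, chrom, strand, tss (0-based)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str,
                                            "strand": str, "tss": np.int64})
    required = {"gene_id", "chrom", "strand", "tss"}
    if not required <= set(df.columns):
        raise ValueError(f"annotation must have columns {sorted(required)}")
    if df.gene_id.duplicated().any():
        raise ValueError("duplicate gene_id in annotation")
    if (df.tss < 0).any():
        raise ValueError("negative TSS coordinate")
    if not df.strand.isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")
    return df


def read_chrom_lengths(path) -> dict:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={"chrom": str, "length": np.int64})
    return dict(zip(df.chrom, df.length))


def read_bed(path) -> IntervalSet:
    """Read BED3+ (0-based half-open); intervals are sorted and merged."""
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED line needs >= 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinate") from exc
            if start >= end:
                raise ValueError(f"{path}:{ln}: start >= end")
            records.append((chrom, start, end))
    return IntervalSet.from_records(records)


def write_bed(intervals: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals.to_records():
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_bedgraph(path) -> PeakTrack:
    """Read a 4-column bedGraph into a per-chromosome step function."""
    by_chrom: dict = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: bedGraph line needs 4 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
                value = float(parts[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed coordinate or value") from exc
            if start >= end:
                raise ValueError(f"{path}:{ln}: start >= end")
            by_chrom.setdefault(chrom, []).append((start, end, value))
    segments = {}
    for chrom, rows in by_chrom.items():
        rows.sort()
        starts = np.array([r[0] for r in rows])
        ends = np.array([r[1] for r in rows])
        values = np.array([r[2] for r in rows])
        segments[chrom] = (starts, ends, values)
    return PeakTrack(segments=segments)  # overlap validation in PeakTrack


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def save_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        if isinstance(o, pd.Index):
            return list(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
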