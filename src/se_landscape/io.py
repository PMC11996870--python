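"""Readers and writers for the on-disk formats the pipeline touches.

BED / ENCODE narrowPeak interval files, TSS annotation tables, per-region
count matrices with library sizes, expression and survival tables, JASPAR
style position frequency matrices, and FASTA sequences.  Coordinates are
read and written 0-based half-open as in BED.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from dataclasses import dataclass

from .intervals import GenomicInterval, Peak, TssRecord


class ParseError(ValueError):
    """A malformed record in an input file; the message names the line."""


@dataclass
class CountsMatrix:
    """Per-region read counts for a panel of samples plus library sizes.

    ``counts`` has shape (n_regions, n_samples), aligned with ``region_ids``
    and ``sample_ids``; ``library_sizes`` is total mapped reads per sample.
    """

    region_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    library_sizes: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        if self.counts.shape != (len(self.region_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match id lists")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(self.library_sizes) != len(self.sample_ids):
            raise ValueError("one library size per sample required")
        if np.any(self.library_sizes <= 0):
            raise ValueError("library sizes must be positive")


def _strip_chr(chrom: str) -> str:
    return chrom[3:] if chrom.startswith("chr") else chrom


def read_peaks(
    path: str | os.PathLike,
    format: str = "narrowPeak",
    sample_id: str = "",
    signal_column: int | None = None,
    strip_chr_prefix: bool = False,
) -> list[Peak]:
    """Read a BED or ENCODE narrowPeak file into a list of peaks.

    For narrowPeak the signal is column 7 (signalValue) unless
    ``signal_column`` (1-based) overrides it; for plain BED it is column 5
    when present, else 1.0.  Scores are parsed as real numbers and not
    capped at 1000 (MACS emits uncapped values).
    """
    if format not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown peak format {format!r}; use 'bed' or 'narrowPeak'")
    min_cols = 10 if format == "narrowPeak" else 3
    sig_idx = (signal_column - 1) if signal_column is not None else 6
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {min_cols} columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise ParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            chrom = _strip_chr(fields[0]) if strip_chr_prefix else fields[0]
            name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else f"peak_{lineno}"
            if format == "narrowPeak":
                try:
                    signal = float(fields[sig_idx])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric signal in column {sig_idx + 1}"
                    ) from exc
            else:
                signal = 1.0
                if len(fields) > 4 and fields[4] not in ("", "."):
                    try:
                        signal = float(fields[4])
                    except ValueError as exc:
                        raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            peaks.append(
                Peak(GenomicInterval(chrom, start, end), signal, name, sample_id)
            )
    return peaks


def read_bed(path: str | os.PathLike, strip_chr_prefix: bool = False) -> list[GenomicInterval]:
    """Read a BED3/BED5 file as bare intervals (name/score kept if present)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise ParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            chrom = _strip_chr(fields[0]) if strip_chr_prefix else fields[0]
            name = fields[3] if len(fields) > 3 and fields[3] != "" else None
            score = None
            if len(fields) > 4 and fields[4] not in ("", "."):
                score = float(fields[4])
            out.append(GenomicInterval(chrom, start, end, name=name, score=score))
    return out


def write_bed(regions: list[GenomicInterval], path: str | os.PathLike) -> None:
    """Write intervals as BED (3, 4 or 5 columns depending on annotations)."""
    with open(path, "w") as fh:
        for iv in regions:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                cols.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                cols.append(f"{iv.score:g}")
            fh.write("\t".join(cols) + "\n")


def read_tss(path: str | os.PathLike) -> list[TssRecord]:
    """Read a TSS annotation TSV with columns gene_id, chrom, pos, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    required = {"gene_id", "chrom", "pos", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ParseError(f"{path}: duplicated gene_id {dup!r}")
    return [
        TssRecord(r.gene_id, r.chrom, int(r.pos), r.strand)
        for r in df.itertuples(index=False)
    ]


def write_tss(records: list[TssRecord], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "gene_id": [t.gene_id for t in records],
            "chrom": [t.chrom for t in records],
            "pos": [t.pos for t in records],
            "strand": [t.strand for t in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_counts(
    counts_path: str | os.PathLike, libsizes_path: str | os.PathLike
) -> CountsMatrix:
    """Read a region x sample counts TSV plus a (sample_id, total_reads) TSV."""
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    libs = pd.read_csv(libsizes_path, sep="\t", index_col=0)["total_reads"]
    missing = [s for s in df.columns if s not in libs.index]
    if missing:
        raise ParseError(f"{libsizes_path}: no library size for samples {missing}")
    return CountsMatrix(
        region_ids=[str(r) for r in df.index],
        sample_ids=[str(s) for s in df.columns],
        counts=df.to_numpy(),
        library_sizes=libs.loc[df.columns].to_numpy(),
    )


def write_counts(cm: CountsMatrix, counts_path: str | os.PathLike, libsizes_path: str | os.PathLike) -> None:
    pd.DataFrame(cm.counts, index=cm.region_ids, columns=cm.sample_ids).rename_axis(
        "region_id"
    ).to_csv(counts_path, sep="\t")
    pd.DataFrame(
        {"sample_id": cm.sample_ids, "total_reads": cm.library_sizes.astype(int)}
    ).to_csv(libsizes_path, sep="\t", index=False)


def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a genes-by-samples (or regions-by-samples) numeric TSV."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_survival(path: str | os.PathLike) -> pd.DataFrame:
    """Read a survival TSV (subject_id, time, event) indexed by subject."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    required = {"subject_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if (df["time"] <= 0).any():
        raise ParseError(f"{path}: times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ParseError(f"{path}: event must be 0 or 1")
    return df.set_index("subject_id")


def read_pfm(path: str | os.PathLike) -> np.ndarray:
    """Read a JASPAR-style position frequency matrix.

    Accepts either four bare whitespace-separated rows in A, C, G, T order,
    or the JASPAR text form ``A [ 1 2 3 ]`` (a ``>header`` line is allowed).
    Returns an (L, 4) count array with columns A, C, G, T.
    """
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(">"):
                continue
            line = line.lstrip("ACGTacgt").strip()
            line = line.replace("[", " ").replace("]", " ")
            vals = [float(tok) for tok in line.split()]
            if vals:
                rows.append(vals)
    if len(rows) != 4:
        raise ParseError(f"{path}: expected 4 base rows, got {len(rows)}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ParseError(f"{path}: ragged matrix rows")
    return np.array(rows, dtype=float).T  # (L, 4)


def write_pfm(counts: np.ndarray, path: str | os.PathLike, name: str = "motif") -> None:
    counts = np.asarray(counts)
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for b, base in enumerate("ACGT"):
            row = " ".join(f"{v:g}" for v in counts[:, b])
            fh.write(f"{base} [ {row} ]\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file as an ordered mapping id -> uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
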