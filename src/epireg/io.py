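"""Readers and writers for the interchange formats the pipeline touches.

Matrices travel as TSV (samples in rows, features in columns, first column
``sample_id``); interval tracks as BED (0-based, half-open); genomes as FASTA;
position weight matrices in MEME minimal motif format; configuration, ground
truth and reports as JSON.  Every writer has a matching reader and round trips
are lossless (values to 1e-12, identifiers exact).
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger("epireg")

BASES = "ACGT"


class FormatError(ValueError):
    """Raised when an input file violates the documented format contract."""


# ---------------------------------------------------------------------------
# Omics matrices
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class OmicsMatrix:
    """One omic's samples-by-features table.

    Parameters
    ----------
    data:
        DataFrame indexed by sample ID with one column per feature.
    kind:
        Feature kind tag, e.g. ``"mrna"``, ``"mirna"`` or ``"meth"``.
    feature_meta:
        Optional per-feature genomic metadata (e.g. ``chrom``/``pos`` for
        methylation sites), indexed by feature ID.
    """

    data: pd.DataFrame
    kind: str = "omics"
    feature_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate sample ID {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate feature ID {dup!r}")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def features(self) -> list[str]:
        return list(self.data.columns)

    def drop_zero_variance(self) -> "OmicsMatrix":
        """Remove features constant across samples (standard input filter)."""
        var = self.data.var(axis=0, ddof=0)
        keep = var > 0
        removed = list(self.data.columns[~keep])
        if removed:
            log.info("dropped %d zero-variance features: %s%s",
                     len(removed), ", ".join(removed[:5]),
                     "..." if len(removed) > 5 else "")
        meta = self.feature_meta
        if meta is not None:
            meta = meta.loc[meta.index.intersection(self.data.columns[keep])]
        return OmicsMatrix(self.data.loc[:, keep], self.kind, meta)


def write_matrix(mat: OmicsMatrix, path: str | Path) -> None:
    out = mat.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_matrix(path: str | Path, kind: str = "omics",
                drop_zero_var: bool = False) -> OmicsMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dup = {f for f in header if header.count(f) > 1}
    if dup:
        raise FormatError(f"{path}: duplicate feature ID {sorted(dup)[0]!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate sample ID {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate feature ID {dup!r}")
    bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
    if len(bad):
        raise FormatError(f"{path}: non-numeric values in column {bad[0]!r}")
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        raise FormatError(f"{path}: missing/ragged cell in column {col!r}")
    mat = OmicsMatrix(df, kind)
    if drop_zero_var:
        mat = mat.drop_zero_variance()
    return mat


# ---------------------------------------------------------------------------
# Genomic intervals (BED, 0-based half-open)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GenomicIntervalSet:
    """Named, optionally strand-aware intervals on a genome (BED convention)."""

    df: pd.DataFrame  # columns: chrom, start, end, name, score, strand

    COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

    def __post_init__(self) -> None:
        df = self.df
        for col, default in (("name", "."), ("score", 0), ("strand", ".")):
            if col not in df.columns:
                df[col] = default
        df = df[self.COLUMNS].reset_index(drop=True)
        if (df["start"] >= df["end"]).any():
            row = df[df["start"] >= df["end"]].iloc[0]
            raise FormatError(
                f"interval {row['name']!r}: start {row.start} >= end {row.end}")
        if (df["chrom"].astype(str).str.len() == 0).any():
            raise FormatError("empty chromosome name")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def by_chrom(self) -> dict[str, pd.DataFrame]:
        return {c: g.sort_values(["start", "end"]).reset_index(drop=True)
                for c, g in self.df.groupby("chrom")}


def write_bed(intervals: GenomicIntervalSet, path: str | Path) -> None:
    intervals.df[GenomicIntervalSet.COLUMNS].to_csv(
        path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> GenomicIntervalSet:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: fewer than 3 BED fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            score_raw = parts[4] if len(parts) > 4 else 0
            try:
                score = int(score_raw)
            except (TypeError, ValueError):
                try:
                    score = float(score_raw)
                except ValueError:
                    score = score_raw
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((chrom, start, end, name, score, strand))
    df = pd.DataFrame(rows, columns=GenomicIntervalSet.COLUMNS)
    return GenomicIntervalSet(df)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences; headers are tokenized at the first whitespace."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise FormatError(f"{path}: no FASTA records")
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def write_meme(pwms: Iterable, path: str | Path) -> None:
    """Write PWMs (objects with .name, .probs (w x 4), .background)."""
    pwms = list(pwms)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        if pwms:
            bg = pwms[0].background
            fh.write("Background letter frequencies\n")
            fh.write(" ".join(f"{b} {f:.6f}" for b, f in zip(BASES, bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.probs.shape[0]}\n")
            for row in pwm.probs:
                fh.write(" " + " ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


def read_meme(path: str | Path, row_tol: float = 1e-3) -> list:
    """Parse MEME minimal format; probability rows off by <= ``row_tol``
    are renormalized, rows further from 1 are rejected."""
    from .motifs import PWM  # local import to avoid a cycle

    background = np.full(4, 0.25)
    pwms: list[PWM] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            toks = lines[i + 1].split()
            freq = {toks[j]: float(toks[j + 1]) for j in range(0, len(toks), 2)}
            background = np.array([freq.get(b, 0.25) for b in BASES])
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            while i < len(lines) and "letter-probability" not in lines[i]:
                i += 1
            if i >= len(lines):
                raise FormatError(f"{path}: motif {name!r} has no matrix header")
            i += 1
            rows = []
            while i < len(lines):
                toks = lines[i].split()
                if len(toks) != 4:
                    break
                try:
                    row = np.array([float(t) for t in toks])
                except ValueError:
                    break
                s = row.sum()
                if abs(s - 1.0) > row_tol:
                    raise FormatError(
                        f"{path}: motif {name!r} row sums to {s:.4f}, not 1")
                rows.append(row / s)
                i += 1
            if not rows:
                raise FormatError(f"{path}: motif {name!r} has an empty matrix")
            pwms.append(PWM(name=name, probs=np.vstack(rows),
                            background=background.copy()))
            continue
        i += 1
    return pwms
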