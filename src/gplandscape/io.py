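"""Readers and writers for landscapes, MAVE tables and sequence collections.

All tabular formats are plain CSV with a ``sequence`` column; complete
landscapes are stored one row per genotype in encoding order.  Natural
sequence collections come in as FASTA files of start-codon-anchored upstream
regions, from which a fixed window is extracted and aggregated to counts.

Coordinate convention for upstream windows: the last base of each record is
position -1 (immediately upstream of the start codon), so a window of
length ``w`` at offset ``o`` covers positions ``-(o + w) .. -(o + 1)``; e.g.
offset 4, length 9 covers -13..-5.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .gp import CountData, GaussianObservations
from .space import Landscape, SequenceSpace

__all__ = [
    "infer_space",
    "read_landscape_csv",
    "write_landscape_csv",
    "read_mave_csv",
    "pool_replicates",
    "read_counts_csv",
    "read_fasta_window",
    "write_posterior_csv",
]


def infer_space(sequences) -> SequenceSpace:
    """Build a space from the symbols observed at each site of a collection."""
    seqs = list(sequences)
    if not seqs:
        raise ValueError("no sequences to infer a space from")
    ell = len(seqs[0])
    if any(len(s) != ell for s in seqs):
        raise ValueError("sequences have unequal lengths")
    alphabets = ["".join(sorted({s[p] for s in seqs})) for p in range(ell)]
    return SequenceSpace(alphabets)


def read_landscape_csv(path, space: SequenceSpace | None = None,
                       require_complete: bool = True) -> Landscape:
    """Read a complete landscape (``sequence,value``) ordered by encoding."""
    df = pd.read_csv(path, dtype={"sequence": str})
    _require_columns(df, ["sequence", "value"], path)
    if space is None:
        space = infer_space(df["sequence"])
    idx = space.encode_many(df["sequence"])
    if require_complete:
        if len(np.unique(idx)) != space.n_genotypes:
            raise ValueError(
                f"{path}: landscape is incomplete "
                f"({len(np.unique(idx))} of {space.n_genotypes} genotypes)"
            )
    values = np.empty(space.n_genotypes)
    values[idx] = df["value"].to_numpy(dtype=float)
    return Landscape(space, values)


def write_landscape_csv(landscape: Landscape, path) -> None:
    pd.DataFrame({
        "sequence": landscape.space.genotype_strings(),
        "value": landscape.values,
    }).to_csv(path, index=False)


def write_posterior_csv(posterior, path, sd: np.ndarray | None = None) -> None:
    """Complete-landscape posterior table: ``sequence,post_mean[,post_sd]``."""
    df = pd.DataFrame({
        "sequence": posterior.space.genotype_strings(),
        "post_mean": posterior.mean,
    })
    if sd is not None:
        df["post_sd"] = sd
    df.to_csv(path, index=False)


def read_mave_csv(path) -> pd.DataFrame:
    """MAVE measurement table: ``sequence,y,var`` or ``sequence,rep1..repN``."""
    df = pd.read_csv(path, dtype={"sequence": str})
    if "sequence" not in df.columns:
        raise ValueError(f"{path}: missing 'sequence' column")
    has_summary = "y" in df.columns
    rep_cols = [c for c in df.columns if c.startswith("rep")]
    if not has_summary and not rep_cols:
        raise ValueError(
            f"{path}: need either a 'y' column or replicate columns 'rep1..'"
        )
    return df


def pool_replicates(table: pd.DataFrame, space: SequenceSpace,
                    sigma2_common: float | str = "estimate"
                    ) -> GaussianObservations:
    """Pool replicate measurements into per-sequence means with noise variances.

    Each sequence's squared standard error is the common measurement variance
    divided by its replicate count, ``sigma_hat^2 / n_i``.  With
    ``sigma2_common="estimate"`` the common variance is pooled from the
    within-sequence spread of replicated measurements.
    """
    rep_cols = [c for c in table.columns if c.startswith("rep")]
    if rep_cols:
        reps = table[rep_cols].to_numpy(dtype=float)
        n_i = np.sum(~np.isnan(reps), axis=1)
        if np.any(n_i == 0):
            raise ValueError("a sequence has zero replicate measurements")
        y = np.nanmean(reps, axis=1)
        if sigma2_common == "estimate":
            dev = reps - y[:, None]
            ss = np.nansum(dev ** 2)
            dof = int(np.sum(n_i - 1))
            if dof == 0:
                raise ValueError("cannot estimate the common variance: "
                                 "no sequence has >= 2 replicates")
            sigma2_common = ss / dof
    else:
        y = table["y"].to_numpy(dtype=float)
        if "var" in table.columns:
            idx = space.encode_many(table["sequence"])
            return GaussianObservations(space, idx, y,
                                        table["var"].to_numpy(dtype=float))
        n_i = np.ones(len(y))
        if sigma2_common == "estimate":
            raise ValueError("cannot estimate a common variance without "
                             "replicate columns")
    idx = space.encode_many(table["sequence"])
    return GaussianObservations(space, idx, y, float(sigma2_common) / n_i)


def read_counts_csv(path, space: SequenceSpace | None = None) -> CountData:
    """Sequence count table: ``sequence,count``."""
    df = pd.read_csv(path, dtype={"sequence": str})
    _require_columns(df, ["sequence", "count"], path)
    if space is None:
        space = infer_space(df["sequence"])
    counts = np.zeros(space.n_genotypes, dtype=np.int64)
    idx = space.encode_many(df["sequence"])
    np.add.at(counts, idx, df["count"].to_numpy(dtype=np.int64))
    return CountData(space, counts)


def read_fasta_window(path, upstream_offset: int, window_len: int,
                      to_rna: bool = False) -> tuple[CountData, dict]:
    """Extract a fixed upstream window from start-codon-anchored records.

    Records hold the region upstream of (and ending immediately before) the
    start codon.  The window at ``upstream_offset`` covers positions
    ``-(offset + window_len) .. -(offset + 1)``; records too short for the
    window or containing symbols outside ACGT(U) in it are dropped and
    counted in the returned stats.
    """
    alphabet = "ACGU" if to_rna else "ACGT"
    windows = []
    n_records = n_short = n_invalid = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        seq = str(rec.seq).upper()
        if to_rna:
            seq = seq.replace("T", "U")
        else:
            seq = seq.replace("U", "T")
        end = len(seq) - upstream_offset
        start = end - window_len
        if start < 0:
            n_short += 1
            continue
        win = seq[start:end]
        if any(ch not in alphabet for ch in win):
            n_invalid += 1
            continue
        windows.append(win)
    if n_records == 0:
        raise ValueError(f"{path}: empty FASTA")
    if not windows:
        raise ValueError(f"{path}: no record yielded a valid window")
    space = SequenceSpace([alphabet] * window_len)
    counts = np.zeros(space.n_genotypes, dtype=np.int64)
    np.add.at(counts, space.encode_many(windows), 1)
    stats = {"n_records": n_records, "n_kept": len(windows),
             "n_too_short": n_short, "n_invalid_symbol": n_invalid}
    return CountData(space, counts), stats


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
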