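"""Readers and writers for the pipeline's on-disk formats.

Formats are deliberately plain text: tab-separated gene x sample count
matrices, GMT gene-set annotations, two-column CSV intensity profiles, and
CSV up-down trial series.  Every reader validates strictly and every
write/read pair is an identity (property-tested).
"""
from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import DEFAULT_FILAMENTS, AnnotationSet, IntensityProfile, UpDownSeries


# ---------------------------------------------------------------------------
# count matrices (TSV, header row of sample names, first column gene ids)

def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample count matrix, rejecting malformed cells.

    Raises
    ------
    ValueError
        On duplicated gene ids, missing cells, or non-integer / negative
        counts; the message names the offending gene and sample.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated gene identifiers {dup[:5]}")
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals.fillna(0))) | (vals < 0)
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raw = df.loc[gene, col]
            raise ValueError(
                f"{path}: invalid count {raw!r} at gene {gene!r}, sample {col!r} "
                "(counts must be nonnegative integers)"
            )
        out[col] = vals.astype(np.int64)
    return out


def write_conditions(conditions: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample": conditions.index, "condition": conditions.values}).to_csv(
        path, sep="\t", index=False
    )


def read_conditions(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "condition"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'sample' and 'condition'")
    if df["sample"].duplicated().any():
        raise ValueError(f"{path}: duplicated sample names")
    return pd.Series(df["condition"].values, index=df["sample"].values, name="condition")


# ---------------------------------------------------------------------------
# GMT gene-set annotations

def read_gmt(path: str | Path) -> AnnotationSet:
    """Parse a GMT file: term id, description, then member genes, tab-separated."""
    terms: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields "
                    f"(term, description, genes); got {len(fields)}"
                )
            term_id, name, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: term {term_id!r} has no member genes")
            if term_id in terms:
                raise ValueError(f"{path}:{lineno}: duplicated term id {term_id!r}")
            terms[term_id] = (name, tuple(genes))
    return AnnotationSet(terms)


def write_gmt(annotation: AnnotationSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term_id, (name, members) in annotation:
            fh.write("\t".join([term_id, name, *members]) + "\n")


# ---------------------------------------------------------------------------
# intensity profiles (CSV: position_mm, intensity)

def write_profile(profile: IntensityProfile, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["position_mm", "intensity"])
        for x, y in zip(profile.positions, profile.intensities):
            writer.writerow([repr(float(x)), repr(float(y))])


def read_profile(path: str | Path, normalized: bool = False) -> IntensityProfile:
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"position_mm", "intensity"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'position_mm' and 'intensity'")
    return IntensityProfile(
        positions=df["position_mm"].to_numpy(float),
        intensities=df["intensity"].to_numpy(float),
        normalized=normalized,
    )


# ---------------------------------------------------------------------------
# up-down series (CSV: order, force_g, response in {X, O}; X = withdrawal)

def write_updown(series: UpDownSeries, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["order", "force_g", "response"])
        for i, (f, r) in enumerate(zip(series.forces, series.responses), start=1):
            writer.writerow([i, repr(float(f)), "X" if r else "O"])


def read_updown(
    path: str | Path,
    filaments: tuple[float, ...] = DEFAULT_FILAMENTS,
    start_g: float = 10.0,
) -> UpDownSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"order", "force_g", "response"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'order', 'force_g', 'response'")
    df = df.sort_values("order")
    symbols = set(df["response"].astype(str))
    if not symbols <= {"X", "O"}:
        raise ValueError(f"{path}: responses must be 'X' (withdrawal) or 'O'; got {sorted(symbols)}")
    return UpDownSeries(
        forces=df["force_g"].to_numpy(float),
        responses=(df["response"].astype(str) == "X").to_numpy(),
        filaments=filaments,
        start_g=start_g,
    )


# ---------------------------------------------------------------------------
# truth tables (TSV)

def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index_label="gene_id")


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
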