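"""In-memory containers shared across the pipeline.

The pipeline operates on four kinds of data: paired gene x sample count
matrices for the transcriptome (RNA) and translatome (ribosome-protected
fragments, RPF) layers, gene-set annotations for over-representation
analysis, 1-D fluorescence intensity profiles sampled along a nerve, and
ordered up-down (staircase) behavioral response series.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

ASSAYS = ("RNA", "RPF")
CONDITIONS = ("control", "treated")

#: Calibrated von Frey filament forces in grams, ascending.
DEFAULT_FILAMENTS = (4.0, 6.0, 8.0, 10.0, 15.0, 26.0, 60.0, 100.0)


def _check_count_matrix(df: pd.DataFrame, name: str) -> None:
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{name}: duplicated gene identifiers {dups[:5]}")
    arr = df.to_numpy()
    if arr.size == 0:
        raise ValueError(f"{name}: empty count matrix")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.issubdtype(arr.dtype, np.number) or not np.all(
            np.asarray(arr, float) == np.floor(np.asarray(arr, float))
        ):
            raise ValueError(f"{name}: counts must be integers")
    if np.any(np.asarray(arr, float) < 0):
        raise ValueError(f"{name}: counts must be nonnegative")


@dataclass
class PairedCounts:
    """Paired RNA / RPF count matrices over an identical gene list.

    Attributes
    ----------
    rna, rpf:
        Integer count matrices, genes (rows) x samples (columns).  Both
        matrices carry the same gene index in the same order.
    rna_conditions, rpf_conditions:
        Per-sample condition labels (``control`` or ``treated``) indexed by
        the corresponding matrix's column names.  Every condition must have
        at least two replicates within each assay.
    """

    rna: pd.DataFrame
    rpf: pd.DataFrame
    rna_conditions: pd.Series
    rpf_conditions: pd.Series

    def __post_init__(self) -> None:
        _check_count_matrix(self.rna, "RNA")
        _check_count_matrix(self.rpf, "RPF")
        if not self.rna.index.equals(self.rpf.index):
            raise ValueError("RNA and RPF matrices must share an identical gene list/order")
        for assay, df, cond in (
            ("RNA", self.rna, self.rna_conditions),
            ("RPF", self.rpf, self.rpf_conditions),
        ):
            cond = pd.Series(cond)
            missing = set(df.columns) - set(cond.index)
            if missing:
                raise ValueError(f"{assay}: samples without condition labels: {sorted(missing)}")
            bad = set(cond.loc[list(df.columns)]) - set(CONDITIONS)
            if bad:
                raise ValueError(f"{assay}: unknown condition labels {sorted(bad)}")
            counts = cond.loc[list(df.columns)].value_counts()
            for c in CONDITIONS:
                if counts.get(c, 0) < 2:
                    raise ValueError(f"{assay}: condition {c!r} needs >= 2 samples")

    @property
    def genes(self) -> pd.Index:
        return self.rna.index

    def matrix(self, assay: str) -> pd.DataFrame:
        if assay not in ASSAYS:
            raise ValueError(f"unknown assay {assay!r}")
        return self.rna if assay == "RNA" else self.rpf

    def conditions(self, assay: str) -> pd.Series:
        if assay not in ASSAYS:
            raise ValueError(f"unknown assay {assay!r}")
        cond = self.rna_conditions if assay == "RNA" else self.rpf_conditions
        cols = self.matrix(assay).columns
        return pd.Series(cond).loc[list(cols)]


@dataclass
class AnnotationSet:
    """Gene-set annotation: term id -> (term name, ordered member genes).

    Member lists are stored in insertion order so that GMT round-trips are
    exact; set semantics are used for all enrichment computations.
    """

    terms: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term_id, (name, members) in self.terms.items():
            members = tuple(members)
            if len(members) < 1:
                raise ValueError(f"term {term_id!r} has no member genes")
            self.terms[term_id] = (name, members)

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms.items())

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def members(self, term_id: str) -> tuple[str, ...]:
        return self.terms[term_id][1]

    def name(self, term_id: str) -> str:
        return self.terms[term_id][0]

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for _, (_, members) in self:
            out.update(members)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return self.terms == other.terms


@dataclass
class IntensityProfile:
    """1-D fluorescence intensity trace along a nerve.

    Positions are millimetres from the crush site (0 = crush), strictly
    increasing.  ``normalized`` marks a profile whose intensities have been
    divided by the crush-site value, so the curve starts near 1.
    """

    positions: np.ndarray
    intensities: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.ndim != 1 or self.positions.shape != self.intensities.shape:
            raise ValueError("positions and intensities must be 1-D arrays of equal length")
        if len(self.positions) < 2:
            raise ValueError("profile needs at least 2 samples")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative")


@dataclass
class UpDownSeries:
    """Ordered up-down (staircase) trial sequence.

    ``responses`` is boolean: True = paw withdrawal, False = no withdrawal.
    Forces must belong to the filament series.
    """

    forces: np.ndarray
    responses: np.ndarray
    filaments: tuple[float, ...] = DEFAULT_FILAMENTS
    start_g: float = 10.0

    def __post_init__(self) -> None:
        self.forces = np.asarray(self.forces, dtype=float)
        self.responses = np.asarray(self.responses, dtype=bool)
        if self.forces.ndim != 1 or self.forces.shape != self.responses.shape:
            raise ValueError("forces and responses must be 1-D arrays of equal length")
        if len(self.forces) < 1:
            raise ValueError("series needs at least one trial")
        self.filaments = tuple(float(f) for f in self.filaments)
        if any(b <= a for a, b in zip(self.filaments, self.filaments[1:])):
            raise ValueError("filament series must be strictly increasing")
        known = set(self.filaments)
        bad = [f for f in self.forces if f not in known]
        if bad:
            raise ValueError(f"forces outside the filament series: {bad[:5]}")

    def __len__(self) -> int:
        return len(self.forces)
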