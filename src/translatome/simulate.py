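"""Synthetic-data generators for every input the pipeline consumes.

Four generators, all deterministic given a seed:

* paired negative-binomial RNA/RPF count matrices with planted regulatory
  classes and a gene-level truth table;
* toy gene-set annotations with optional planted over-representation;
* exponentially decaying fluorescence intensity profiles with
  multiplicative Gaussian noise;
* up-down (staircase) behavioral response sequences driven by a logistic
  psychometric function of log10 force.

The defaults encode the two-condition (control shRNA vs knockdown) design
the pipeline is built around; see ``SimConfig``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .containers import DEFAULT_FILAMENTS, AnnotationSet, IntensityProfile, PairedCounts, UpDownSeries

CLASSES = ("translation_only", "transcription_only", "opposite", "concordant", "null")

_DEFAULT_CLASS_COUNTS = {
    "translation_only": 150,
    "transcription_only": 150,
    "opposite": 50,
    "concordant": 50,
    "null": 1600,
}


@dataclass
class SimConfig:
    """Configuration of the paired-counts generator.

    Parameters
    ----------
    n_genes:
        Total number of genes; must equal the sum of ``class_counts``.
    class_counts:
        Genes per regulatory class.  ``translation_only`` genes change only
        in the RPF layer, ``transcription_only`` only in the RNA layer,
        ``opposite`` in both layers with opposing signs, ``concordant`` in
        both with the same sign, ``null`` in neither.
    effect_log2fc:
        Magnitude of the planted effect, log2 units.
    dispersion:
        Negative-binomial dispersion alpha; variance = mu + alpha * mu^2.
    base_mean_range:
        Per-gene baseline means are drawn log-uniformly over this range,
        spanning low- and high-expression genes.
    n_replicates:
        Replicates per condition per assay (>= 2).
    libsize_factors:
        Optional per-sample library-size multipliers, length
        ``2 * n_replicates`` (control replicates first), applied to both
        assays; defaults to 1 everywhere.
    """

    n_genes: int = 2000
    class_counts: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_CLASS_COUNTS))
    effect_log2fc: float = 2.0
    dispersion: float = 0.05
    base_mean_range: tuple[float, float] = (10.0, 10_000.0)
    n_replicates: int = 3
    libsize_factors: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.class_counts) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown regulatory classes {sorted(unknown)}")
        for c in CLASSES:
            self.class_counts.setdefault(c, 0)
        if any(v < 0 for v in self.class_counts.values()):
            raise ValueError("class counts must be nonnegative")
        if sum(self.class_counts.values()) != self.n_genes:
            raise ValueError(
                f"class counts sum to {sum(self.class_counts.values())}, expected n_genes={self.n_genes}"
            )
        if self.effect_log2fc <= 0:
            raise ValueError("effect_log2fc must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        lo, hi = self.base_mean_range
        if lo <= 0 or hi < lo:
            raise ValueError("base_mean_range must be positive with lo <= hi")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per condition")
        if self.libsize_factors is not None:
            self.libsize_factors = tuple(float(s) for s in self.libsize_factors)
            if len(self.libsize_factors) != 2 * self.n_replicates:
                raise ValueError("libsize_factors must have length 2 * n_replicates")
            if any(s <= 0 for s in self.libsize_factors):
                raise ValueError("library-size factors must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "base_mean_range" in raw:
            raw["base_mean_range"] = tuple(raw["base_mean_range"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "n_genes": self.n_genes,
            "class_counts": dict(self.class_counts),
            "effect_log2fc": self.effect_log2fc,
            "dispersion": self.dispersion,
            "base_mean_range": list(self.base_mean_range),
            "n_replicates": self.n_replicates,
            "libsize_factors": list(self.libsize_factors) if self.libsize_factors else None,
            "seed": self.seed,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB draw parameterized by (mean, dispersion alpha): var = mu + alpha mu^2.

    For very small alpha the NB degenerates to Poisson; sample the limit
    directly to avoid overflow in the size parameter.
    """
    if alpha < 1e-8:
        return rng.poisson(mean)
    size = 1.0 / alpha
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_paired_counts(config: SimConfig) -> tuple[PairedCounts, pd.DataFrame]:
    """Generate paired RNA/RPF count matrices plus a gene-level truth table.

    Counts for gene g in sample j are NB with mean
    ``s_j * mu_g * 2**lfc`` where ``lfc`` is the planted per-layer effect in
    treated samples and 0 otherwise.  RNA and RPF draws are independent
    given their means.  The truth table records, per gene, the planted class,
    per-layer log2 fold changes and the effect direction.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = [f"g{i:05d}" for i in range(n)]

    lo, hi = config.base_mean_range
    base = 10 ** rng.uniform(np.log10(lo), np.log10(hi), size=n)

    classes = np.concatenate(
        [np.full(config.class_counts[c], c, dtype=object) for c in CLASSES]
    )
    sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    e = config.effect_log2fc
    lfc_rna = np.zeros(n)
    lfc_rpf = np.zeros(n)
    for i, c in enumerate(classes):
        if c == "transcription_only":
            lfc_rna[i] = sign[i] * e
        elif c == "translation_only":
            lfc_rpf[i] = sign[i] * e
        elif c == "opposite":
            lfc_rna[i] = sign[i] * e
            lfc_rpf[i] = -sign[i] * e
        elif c == "concordant":
            lfc_rna[i] = sign[i] * e
            lfc_rpf[i] = sign[i] * e

    m = config.n_replicates
    s = np.asarray(config.libsize_factors if config.libsize_factors else [1.0] * (2 * m))
    cond = ["control"] * m + ["treated"] * m
    treated = np.array([c == "treated" for c in cond], dtype=float)

    frames: dict[str, pd.DataFrame] = {}
    for assay, lfc in (("RNA", lfc_rna), ("RPF", lfc_rpf)):
        # genes x samples mean matrix
        mu = base[:, None] * (2.0 ** (lfc[:, None] * treated[None, :])) * s[None, :]
        counts = _nb_sample(rng, mu, config.dispersion)
        cols = [f"{assay}_{c}_{i % m + 1}" for i, c in enumerate(cond)]
        frames[assay] = pd.DataFrame(counts, index=genes, columns=cols)

    conditions = {assay: pd.Series(cond, index=frames[assay].columns) for assay in frames}
    paired = PairedCounts(
        rna=frames["RNA"],
        rpf=frames["RPF"],
        rna_conditions=conditions["RNA"],
        rpf_conditions=conditions["RPF"],
    )

    direction = np.where(classes == "null", "none", np.where(sign > 0, "up", "down"))
    truth = pd.DataFrame(
        {
            "true_class": classes,
            "true_log2fc_rna": lfc_rna,
            "true_log2fc_rpf": lfc_rpf,
            "direction": direction,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return paired, truth


def simulate_annotation(
    universe: Sequence[str],
    n_terms: int,
    planted: Mapping[str, tuple[int, float] | Sequence[str]] | None = None,
    query: Sequence[str] | None = None,
    size_range: tuple[int, int] = (10, 60),
    seed: int = 0,
) -> AnnotationSet:
    """Build a toy annotation with optional planted over-representation.

    ``planted`` maps a term id either to an explicit member gene list, or to
    ``(size, strength)``: ``size`` members are drawn without replacement with
    sampling weight ``strength`` for genes in ``query`` and 1 elsewhere, so
    ``strength = 1`` reproduces the uniform background and large values
    concentrate the term on the query list.  ``n_terms`` background terms
    draw members uniformly from the universe.
    """
    rng = np.random.default_rng(seed)
    universe = list(universe)
    uset = set(universe)
    if n_terms < 0:
        raise ValueError("n_terms must be nonnegative")
    terms: dict[str, tuple[str, tuple[str, ...]]] = {}

    for name, spec in (planted or {}).items():
        if isinstance(spec, tuple) and len(spec) == 2 and isinstance(spec[0], (int, np.integer)):
            size, strength = int(spec[0]), float(spec[1])
            if size < 1:
                raise ValueError(f"planted term {name!r} must have >= 1 member")
            if size > len(universe):
                raise ValueError(f"planted term {name!r} larger than the universe")
            if strength <= 0 or not np.isfinite(strength):
                raise ValueError("enrichment strength must be positive and finite")
            if strength != 1.0:
                if query is None:
                    raise ValueError("a query list is required for weighted planting")
                qset = set(query)
                w = np.array([strength if g in qset else 1.0 for g in universe])
                members = rng.choice(universe, size=size, replace=False, p=w / w.sum())
            else:
                members = rng.choice(universe, size=size, replace=False)
            terms[name] = (name, tuple(members))
        else:
            members = list(spec)
            if len(members) < 1:
                raise ValueError(f"planted term {name!r} must have >= 1 member")
            if not set(members) <= uset:
                raise ValueError(f"planted term {name!r} has members outside the universe")
            terms[name] = (name, tuple(members))

    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValueError("size_range must satisfy 1 <= lo <= hi")
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(universe))
        members = rng.choice(universe, size=size, replace=False)
        terms[f"BG:{i:04d}"] = (f"background term {i}", tuple(members))
    return AnnotationSet(terms)


def simulate_intensity_profile(
    lambda_mm: float,
    length_mm: float = 6.0,
    step_mm: float = 0.01,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> IntensityProfile:
    """Exponential decay I(x) = exp(-x/lambda) * (1 + eps), eps ~ N(0, sd^2).

    Positions start at 0 (the crush site) and advance by ``step_mm``;
    intensities are truncated at zero.  Emulates a crush-normalized axonal
    marker trace along the nerve.
    """
    if lambda_mm <= 0:
        raise ValueError("decay length lambda_mm must be positive")
    if step_mm <= 0 or length_mm < step_mm:
        raise ValueError("need step_mm > 0 and length_mm >= step_mm")
    rng = np.random.default_rng(seed)
    x = np.arange(0.0, length_mm + step_mm / 2, step_mm)
    clean = np.exp(-x / lambda_mm)
    noise = rng.normal(0.0, noise_sd, size=x.shape) if noise_sd > 0 else 0.0
    y = np.clip(clean * (1.0 + noise), 0.0, None)
    return IntensityProfile(positions=x, intensities=y, normalized=False)


def simulate_updown_series(
    true_threshold_g: float,
    slope: float = 10.0,
    filaments: Sequence[float] = DEFAULT_FILAMENTS,
    start_g: float = 10.0,
    n_after_crossing: int = 4,
    seed: int = 0,
    max_trials: int = 50,
) -> UpDownSeries:
    """Simulate an up-down trial sequence.

    Withdrawal probability follows a logistic psychometric function of
    log10 force centered at the true threshold:
    ``P(withdraw | F) = expit(slope * (log10 F - log10 threshold))``.

    The staircase starts at ``start_g``, steps down one filament after a
    withdrawal and up after none, clamped at the series bounds.  After the
    first pair of unlike responses (the threshold crossing),
    ``n_after_crossing`` further stimuli are applied.  A non-response at the
    strongest filament terminates the series (the 100 g ceiling rule); two
    consecutive responses at the weakest filament before any crossing
    terminate it as floor-censored.
    """
    if true_threshold_g <= 0:
        raise ValueError("true threshold must be positive")
    filaments = tuple(float(f) for f in filaments)
    if any(b <= a for a, b in zip(filaments, filaments[1:])):
        raise ValueError("filaments must be strictly increasing")
    if start_g not in filaments:
        raise ValueError(f"starting force {start_g} g is not in the filament series")
    rng = np.random.default_rng(seed)
    logf = np.log10(filaments)
    log_thr = np.log10(true_threshold_g)

    idx = filaments.index(start_g)
    forces: list[float] = []
    responses: list[bool] = []
    crossed = False
    remaining = None
    for _ in range(max_trials):
        f = filaments[idx]
        p = float(expit(slope * (np.log10(f) - log_thr)))
        r = bool(rng.random() < p)
        forces.append(f)
        responses.append(r)

        if not crossed and len(responses) >= 2 and responses[-1] != responses[-2]:
            crossed = True
            remaining = n_after_crossing
        elif crossed:
            remaining -= 1
        if not r and idx == len(filaments) - 1:
            break  # ceiling: no response at the strongest filament
        if crossed and remaining == 0:
            break
        if (
            not crossed
            and r
            and idx == 0
            and len(responses) >= 2
            and responses[-2]
            and forces[-2] == filaments[0]
        ):
            break  # floor-censored: repeated responses at the weakest filament
        idx += -1 if r else 1
        idx = min(max(idx, 0), len(filaments) - 1)
    return UpDownSeries(
        forces=np.array(forces),
        responses=np.array(responses),
        filaments=filaments,
        start_g=start_g,
    )
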