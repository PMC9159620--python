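"""Mechanical withdrawal thresholds and thermal latency summaries.

The 50% paw withdrawal threshold is estimated from an up-down (staircase)
von Frey series: testing starts at 10 g in the middle of the filament
series (4, 6, 8, 10, 15, 26, 60, 100 g), steps down after a withdrawal and
up after none, and continues for four stimuli beyond the first threshold
crossing.  The estimate is

    threshold = 10 ** (X_f + k * delta)

where X_f is log10 of the final tested force, delta is the mean absolute
log10 spacing of the filament series, and k is the up-down correction
constant for the observed response pattern.  Here k is obtained as the
maximum-likelihood location of a normal psychometric function of log10
force with spread fixed at delta — the statistical model underlying the
classical tabulated constants — so k adapts to the exact sequence tested.
Animals that never withdraw are assigned the 100 g ceiling; animals that
withdraw at every presentation are assigned the weakest filament.

Thermal (radiant heat) latencies are summarized as the mean of three
repetitions with a 30 s cutoff; values at the cutoff are censored.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import DEFAULT_FILAMENTS, UpDownSeries

LATENCY_CUTOFF_S = 30.0


def log_step(filaments: tuple[float, ...] = DEFAULT_FILAMENTS) -> float:
    """Mean absolute log10 spacing of the filament series (delta)."""
    logs = np.log10(np.asarray(filaments, float))
    return float(np.mean(np.abs(np.diff(logs))))


def _psychometric_nll(mu: float, logf: np.ndarray, resp: np.ndarray, sigma: float) -> float:
    z = (logf - mu) / sigma
    # P(withdraw | force) = Phi((x - mu)/sigma)
    logp = stats.norm.logcdf(z)
    logq = stats.norm.logcdf(-z)
    return float(-(np.sum(logp[resp]) + np.sum(logq[~resp])))


def dixon_k(series: UpDownSeries, delta: float | None = None) -> float:
    """Up-down correction constant for the observed sequence.

    Maximizes the likelihood of the trial responses under a normal
    psychometric function on log10 force with spread ``delta`` and returns
    k = (mu_hat - X_f) / delta, the offset of the estimated 50% point from
    the final tested force in units of the filament spacing.
    """
    if delta is None:
        delta = log_step(series.filaments)
    logf = np.log10(series.forces)
    resp = series.responses
    if resp.all() or (~resp).all():
        raise ValueError("k is undefined without both response types; apply the boundary rules")
    lo = np.log10(series.filaments[0]) - 2 * delta
    hi = np.log10(series.filaments[-1]) + 2 * delta
    res = optimize.minimize_scalar(
        _psychometric_nll,
        bounds=(lo, hi),
        args=(logf, resp, delta),
        method="bounded",
        options={"xatol": 1e-10},
    )
    mu_hat = float(res.x)
    return (mu_hat - float(logf[-1])) / delta


def updown_threshold(
    series: UpDownSeries,
    method: str = "dixon",
    validate: bool = True,
) -> float:
    """50% withdrawal threshold (grams) from an up-down series.

    Boundary conventions: a series with no withdrawal at any filament is
    assigned the ceiling (strongest filament, 100 g in the standard series);
    withdrawal at every presentation is assigned the weakest filament.
    Otherwise the up-down formula is applied (``method='dixon'``), or the
    geometric midpoint of the final reversal pair (``method='midpoint'``).
    Estimates are clamped to the filament range.
    """
    if method not in ("dixon", "midpoint"):
        raise ValueError("method must be 'dixon' or 'midpoint'")
    if validate:
        violations = validate_protocol(series)
        if violations:
            raise ValueError(f"protocol violation: {violations[0]}")
    resp = series.responses
    fmin, fmax = series.filaments[0], series.filaments[-1]
    if not resp.any():
        return float(fmax)
    if resp.all():
        return float(fmin)
    delta = log_step(series.filaments)
    xf = float(np.log10(series.forces[-1]))
    if method == "dixon":
        k = dixon_k(series, delta)
        est = 10 ** (xf + k * delta)
    else:
        x_prev = float(np.log10(series.forces[-2])) if len(series) >= 2 else xf
        est = 10 ** ((xf + x_prev) / 2)
    return float(min(max(est, fmin), fmax))


def validate_protocol(
    series: UpDownSeries,
    n_after_crossing: int = 4,
) -> list[str]:
    """Check a series against the staircase protocol; returns violations.

    Checks the start force, the one-step-down-after-withdrawal /
    one-step-up-after-none rule (clamped at the bounds), early termination
    at a non-response on the strongest filament, and the
    ``n_after_crossing`` additional stimuli after the first pair of unlike
    responses.  Violations are reported, not raised.
    """
    v: list[str] = []
    filaments = series.filaments
    forces = series.forces
    resp = series.responses
    n = len(forces)
    index = {f: i for i, f in enumerate(filaments)}
    if forces[0] != series.start_g:
        v.append(f"trial 1: start force {forces[0]} g, expected {series.start_g} g")
    for i in range(1, n):
        prev = index[forces[i - 1]]
        expected = prev - 1 if resp[i - 1] else prev + 1
        expected = min(max(expected, 0), len(filaments) - 1)
        if index[forces[i]] != expected:
            v.append(
                f"trial {i + 1}: force {forces[i]} g does not follow the "
                f"{'down' if resp[i - 1] else 'up'} rule from {forces[i - 1]} g"
            )
    # ceiling rule: a non-response at the strongest filament ends the series
    for i in range(n - 1):
        if forces[i] == filaments[-1] and not resp[i]:
            v.append(f"trial {i + 1}: series continued after non-response at {filaments[-1]} g")
            break
    # trial count after the first crossing
    cross = None
    for i in range(1, n):
        if resp[i] != resp[i - 1]:
            cross = i
            break
    ceiling_end = forces[-1] == filaments[-1] and not resp[-1]
    floor_end = (
        n >= 2 and forces[-1] == filaments[0] and resp[-1] and forces[-2] == filaments[0] and resp[-2]
    )
    if cross is not None:
        expected_n = cross + 1 + n_after_crossing
        if n > expected_n:
            v.append(f"{n} trials recorded, expected {expected_n} (crossing + {n_after_crossing})")
        elif n < expected_n and not ceiling_end:
            v.append(
                f"{n} trials recorded, expected {expected_n} (crossing + {n_after_crossing})"
            )
    elif not (ceiling_end or floor_end):
        v.append("series ended before the threshold was crossed")
    return v


def latency_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per animal/timepoint mean withdrawal latency and censored fraction.

    ``records`` is long-format with columns ``animal``, ``timepoint`` and
    ``latency_s`` (three repetitions per animal and timepoint).  Latencies
    must lie in (0, 30]; values at the 30 s cutoff count as censored.
    """
    required = {"animal", "timepoint", "latency_s"}
    if not required <= set(records.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    lat = records["latency_s"].to_numpy(float)
    if np.any(lat <= 0) or np.any(lat > LATENCY_CUTOFF_S):
        raise ValueError(f"latencies must lie in (0, {LATENCY_CUTOFF_S}] seconds")
    grouped = records.groupby(["animal", "timepoint"])["latency_s"]
    sizes = grouped.size()
    if (sizes != 3).any():
        bad = sizes.index[sizes != 3][0]
        raise ValueError(f"animal/timepoint {bad} has {sizes[bad]} repetitions, expected 3")
    out = grouped.agg(
        mean_latency_s="mean",
        censored_fraction=lambda x: float(np.mean(np.isclose(x, LATENCY_CUTOFF_S))),
    ).reset_index()
    return out
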