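"""One-phase exponential decay fitting for timestamped plasma-cell cohorts.

A cohort of plasma cells fluorescently labeled at a single moment
("timestamped") declines over weeks to months. Absolute labeled-cell counts
over days are fitted with the one-phase decay model

    count(t) = (N0 - plateau) * exp(-k * t) + plateau,

and the half-life t_1/2 = ln 2 / k is reported. Fitting is nonlinear least
squares on raw counts; a log-linear regression on positive counts seeds the
optimizer. Half-life differences between cohorts are assessed by a
case-resampling bootstrap over per-timepoint replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DecaySeries",
    "DecayFit",
    "HalfLifeComparison",
    "fit_one_phase_decay",
    "compare_half_lives",
]

# a rate decaying less than this fraction over the whole observed span is
# indistinguishable from no decay and reports an infinite half-life
_DECAY_FRACTION_EPS = 1e-6


@dataclass
class DecaySeries:
    """Labeled-cohort counts over days, possibly with replicates.

    ``timepoints`` and ``counts`` are parallel per-observation arrays (a
    timepoint repeats once per replicate); ``replicate_ids`` ties
    observations to replicates for bootstrap resampling.
    """

    timepoints: np.ndarray
    counts: np.ndarray
    replicate_ids: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.timepoints.shape != self.counts.shape:
            raise ValueError("timepoints and counts must have equal length")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.replicate_ids is not None:
            self.replicate_ids = np.asarray(self.replicate_ids)
            if self.replicate_ids.shape != self.timepoints.shape:
                raise ValueError("replicate_ids length mismatch")

    @property
    def unique_timepoints(self) -> np.ndarray:
        return np.unique(self.timepoints)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"day": self.timepoints, "count": self.counts})
        if self.replicate_ids is not None:
            df["replicate_id"] = self.replicate_ids
        for key, val in self.metadata.items():
            df[key] = val
        return df


@dataclass
class DecayFit:
    n0: float
    k: float                 # per day
    plateau: float
    t_half: float            # days; inf when k is at machine scale
    rss: float
    converged: bool
    plateau_mode: str
    t_half_ci: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "n0": self.n0,
            "k_per_day": self.k,
            "plateau": self.plateau,
            "t_half_days": self.t_half,
            "rss": self.rss,
            "converged": self.converged,
            "plateau_mode": self.plateau_mode,
            "t_half_ci": list(self.t_half_ci) if self.t_half_ci else None,
        }


def _log_linear_init(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Seed (n0, k) from a straight-line fit to log counts."""
    pos = y > 0
    if pos.sum() >= 2 and np.unique(t[pos]).size >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        return float(np.exp(intercept)), float(max(-slope, 1e-6))
    return float(y.max() if y.size else 1.0), 1e-2


def fit_one_phase_decay(
    series: DecaySeries, plateau_mode: str = "fixed_zero"
) -> DecayFit:
    """Nonlinear least-squares fit of the one-phase decay model.

    ``plateau_mode="fixed_zero"`` (default) fits ``(n0, k)`` with the plateau
    pinned at 0 and needs >=3 distinct timepoints; ``"free"`` also fits the
    plateau and needs >=4. Non-convergence is flagged on the result, never
    silently replaced. A rate at machine scale reports an infinite
    half-life.
    """
    t = series.timepoints
    y = series.counts
    if plateau_mode not in ("fixed_zero", "free"):
        raise ValueError(f"unknown plateau_mode {plateau_mode!r}")
    n_distinct = series.unique_timepoints.size
    needed = 3 if plateau_mode == "fixed_zero" else 4
    if n_distinct < needed:
        raise ValueError(
            f"{plateau_mode} fit needs >={needed} distinct timepoints, got {n_distinct}"
        )
    if not (y > 0).any():
        raise ValueError("all counts are zero; nothing to fit")

    n0_init, k_init = _log_linear_init(t, y)
    converged = True
    if plateau_mode == "fixed_zero":
        model = lambda tt, n0, k: n0 * np.exp(-k * tt)
        p0 = [n0_init, k_init]
        bounds = ([0.0, 0.0], [np.inf, np.inf])
    else:
        model = lambda tt, n0, k, plateau: (n0 - plateau) * np.exp(-k * tt) + plateau
        p0 = [n0_init, k_init, max(y.min(), 0.0)]
        bounds = ([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf])
    try:
        popt, _ = curve_fit(model, t, y, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError:
        popt = np.asarray(p0, dtype=float)
        converged = False
    resid = y - model(t, *popt)
    n0 = float(popt[0])
    k = float(popt[1])
    plateau = float(popt[2]) if plateau_mode == "free" else 0.0
    t_span = float(t.max() - t.min())
    t_half = np.log(2) / k if k * t_span > _DECAY_FRACTION_EPS else np.inf
    return DecayFit(
        n0=n0,
        k=k,
        plateau=plateau,
        t_half=float(t_half),
        rss=float(resid @ resid),
        converged=converged,
        plateau_mode=plateau_mode,
    )


@dataclass
class HalfLifeComparison:
    delta_t_half: float
    ci_low: float
    ci_high: float
    n_boot: int
    boot_deltas: np.ndarray

    @property
    def excludes_zero(self) -> bool:
        return self.ci_low > 0 or self.ci_high < 0


def _resample_series(series: DecaySeries, rng: np.random.Generator) -> DecaySeries:
    """Resample replicates with replacement within each timepoint."""
    t_out, y_out = [], []
    for tp in series.unique_timepoints:
        sel = np.flatnonzero(series.timepoints == tp)
        pick = rng.choice(sel, size=sel.size, replace=True)
        t_out.append(series.timepoints[pick])
        y_out.append(series.counts[pick])
    return DecaySeries(np.concatenate(t_out), np.concatenate(y_out))


def compare_half_lives(
    fit_a: DecayFit,
    fit_b: DecayFit,
    series_a: DecaySeries,
    series_b: DecaySeries,
    n_boot: int = 500,
    seed: int | None = None,
    ci: float = 0.95,
) -> HalfLifeComparison:
    """Bootstrap difference in half-lives between two cohorts.

    Case-resamples replicates within each timepoint of both series, refits,
    and reports the percentile confidence interval of
    ``t_half(a) - t_half(b)``. Requires both input fits to have converged and
    at least two replicates per timepoint in each series.
    """
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("both fits must have converged")
    for name, s in (("a", series_a), ("b", series_b)):
        for tp in s.unique_timepoints:
            if (s.timepoints == tp).sum() < 2:
                raise ValueError(
                    f"series {name}: timepoint {tp} has <2 replicates; bootstrap undefined"
                )
    rng = np.random.default_rng(seed)
    mode = fit_a.plateau_mode
    deltas = np.empty(n_boot)
    kept = 0
    for _ in range(n_boot):
        ra = fit_one_phase_decay(_resample_series(series_a, rng), mode)
        rb = fit_one_phase_decay(_resample_series(series_b, rng), mode)
        if ra.converged and rb.converged and np.isfinite(ra.t_half) and np.isfinite(rb.t_half):
            deltas[kept] = ra.t_half - rb.t_half
            kept += 1
    deltas = deltas[:kept]
    alpha = (1 - ci) / 2
    lo, hi = np.quantile(deltas, [alpha, 1 - alpha])
    return HalfLifeComparison(
        delta_t_half=fit_a.t_half - fit_b.t_half,
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=kept,
        boot_deltas=deltas,
    )
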