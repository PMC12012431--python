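"""Scale/Γ fitting, model-comparison statistics and synthetic measurements.

The transfer-function models predict heating only up to a global scale
(ΔT = s·|V|²).  For the unity and SEM models that scale is the single free
parameter and has a closed-form least-squares solution; the TLM adds the
reflection coefficient Γ, fitted by a dense grid search with golden-section
refinement.  Models are compared with RMSE and the ordinary-least-squares
AIC, and agreement with measurements is summarized with Bland–Altman limits
of agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "MeasurementSet",
    "FitResult",
    "fit_scale",
    "fit_scale_and_gamma",
    "aic_ols",
    "rmse",
    "bland_altman",
    "synthesize_measurements",
]


@dataclass(frozen=True)
class MeasurementSet:
    """Measured lead-tip temperature rises, one per wire.

    ``errors`` holds per-wire combined measurement uncertainties (°C, the
    quadrature sum of probe spread, transmit-gain fluctuation and baseline
    drift); they are carried for reporting, not used as fit weights.
    """

    names: tuple[str, ...]
    delta_t: np.ndarray  # °C, >= 0
    errors: np.ndarray | None = None

    def __post_init__(self) -> None:
        dt = np.asarray(self.delta_t, dtype=float)
        if dt.ndim != 1 or len(self.names) != dt.size:
            raise ValueError("names and delta_t lengths differ")
        if np.any(dt < 0):
            raise ValueError("temperature rises must be >= 0")
        object.__setattr__(self, "delta_t", dt)
        if self.errors is not None:
            err = np.asarray(self.errors, dtype=float)
            if err.shape != dt.shape or np.any(err < 0):
                raise ValueError("errors must be non-negative, same length as delta_t")
            object.__setattr__(self, "errors", err)

    def __len__(self) -> int:
        return self.delta_t.size


@dataclass(frozen=True)
class FitResult:
    """Fitted model summary: scale (and Γ), residuals, RMSE, AIC."""

    kind: str
    scale: float
    gamma: float | None
    residuals: np.ndarray
    rmse: float
    aic: float
    n_free_parameters: int


def _closed_form_scale(vsq: np.ndarray, measured: np.ndarray) -> float:
    denom = float(np.sum(vsq**2))
    if denom == 0:
        raise ValueError("all |V|^2 predictions are zero; scale fit is degenerate")
    return float(np.sum(measured * vsq) / denom)


def fit_scale(
    vsq: Sequence[float], measured: MeasurementSet, kind: str = "sem"
) -> FitResult:
    """Least-squares global scale for a one-parameter model.

    Minimizes Σ(ΔT_i - s·|V_i|²)²; the optimum is
    s = Σ(ΔT·|V|²) / Σ(|V|⁴).
    """
    v = np.asarray(vsq, dtype=float)
    if v.size != len(measured) or v.size < 2:
        raise ValueError("need >= 2 matching predictions and measurements")
    s = _closed_form_scale(v, measured.delta_t)
    resid = measured.delta_t - s * v
    rss = float(np.sum(resid**2))
    n = v.size
    return FitResult(
        kind=kind,
        scale=s,
        gamma=None,
        residuals=resid,
        rmse=rmse(resid),
        aic=aic_ols(rss, n, 1) if rss > 0 else -math.inf,
        n_free_parameters=1,
    )


def fit_scale_and_gamma(
    voltage_fn: Callable[[float], np.ndarray],
    measured: MeasurementSet,
    grid_step: float = 0.001,
    refine_tol: float = 1e-4,
) -> FitResult:
    """Fit the TLM's reflection coefficient Γ ∈ [0, 1) and global scale.

    ``voltage_fn(gamma)`` must return the |V|² predictions for every wire at
    that Γ.  The outer Γ search is a dense grid (default step 0.001) followed
    by bounded golden-section refinement between the grid neighbours of the
    best point (to ``refine_tol``); the inner scale is closed-form at each Γ.
    Deterministic for given inputs.
    """
    if not 0 < grid_step < 1:
        raise ValueError("grid_step must be in (0, 1)")

    def rss_at(gamma: float) -> float:
        v = np.asarray(voltage_fn(gamma), dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite |V|^2 prediction at gamma = {gamma}")
        s = _closed_form_scale(v, measured.delta_t)
        return float(np.sum((measured.delta_t - s * v) ** 2))

    grid = np.arange(0.0, 1.0, grid_step)
    rss_grid = np.array([rss_at(g) for g in grid])
    i = int(np.argmin(rss_grid))
    lo = grid[max(i - 1, 0)]
    hi = min(grid[i] + grid_step, 1.0 - 1e-9)
    res = minimize_scalar(
        rss_at, bounds=(lo, hi), method="bounded", options={"xatol": refine_tol}
    )
    gamma = float(res.x) if res.fun <= rss_grid[i] else float(grid[i])

    v = np.asarray(voltage_fn(gamma), dtype=float)
    s = _closed_form_scale(v, measured.delta_t)
    resid = measured.delta_t - s * v
    rss = float(np.sum(resid**2))
    n = v.size
    return FitResult(
        kind="tlm",
        scale=s,
        gamma=gamma,
        residuals=resid,
        rmse=rmse(resid),
        aic=aic_ols(rss, n, 2) if rss > 0 else -math.inf,
        n_free_parameters=2,
    )


def rmse(residuals: Sequence[float]) -> float:
    """Root-mean-square of the residuals, √(RSS/n)."""
    r = np.asarray(residuals, dtype=float)
    if r.size == 0:
        raise ValueError("empty residual vector")
    return float(np.sqrt(np.mean(r**2)))


def aic_ols(rss: float, n: int, k: int) -> float:
    """Ordinary-least-squares Akaike information criterion.

    AIC = n·ln(RSS/n) + 2(K+1), where K is the number of free model
    parameters and the +1 accounts for the estimated error variance.
    """
    if rss <= 0:
        raise ValueError(f"RSS must be positive, got {rss}")
    if n <= k + 1:
        raise ValueError(f"need n > K+1, got n={n}, K={k}")
    return n * math.log(rss / n) + 2.0 * (k + 1)


def bland_altman(
    model_vals: Sequence[float], measured_vals: Sequence[float]
) -> dict[str, float]:
    """Bland–Altman agreement summary of model vs measured values.

    Returns the mean difference (model − measured) and the 95% limits of
    agreement, mean ± 1.96·SD with the sample (n−1) standard deviation.
    """
    a = np.asarray(model_vals, dtype=float)
    b = np.asarray(measured_vals, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length arrays with >= 2 entries")
    diff = a - b
    mean = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    return {
        "mean_diff": mean,
        "lower_loa": mean - 1.96 * sd,
        "upper_loa": mean + 1.96 * sd,
    }


def synthesize_measurements(
    names: Sequence[str],
    vsq: Sequence[float],
    true_scale: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> MeasurementSet:
    """Generate synthetic temperature-rise measurements ΔT = s·|V|² + ε.

    ε is iid Normal(0, noise_sd); results are clipped at 0 °C (a fluoroptic
    probe cannot report a negative rise under RF deposition) and reproducible
    for a given ``seed``.  Reported per-wire errors are set to ``noise_sd``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    v = np.asarray(vsq, dtype=float)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=v.size) if noise_sd > 0 else 0.0
    dt = np.clip(true_scale * v + noise, 0.0, None)
    return MeasurementSet(
        names=tuple(names),
        delta_t=dt,
        errors=np.full(v.size, noise_sd),
    )
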