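"""Probabilistic sensitivity analysis on the cost-effectiveness plane.

Two Monte Carlo engines produce a cloud of per-trial incremental cost
(treatment minus comparator, in thousands of 2010 dollars) and incremental
effect (QALYs):

* a nonparametric patient-level bootstrap that resamples each arm with
  replacement to its original size and recomputes winsorized mean lifetime
  cost and mean lifetime QALYs per arm (the default for trial data);
* a parametric engine drawing each arm's mean cost and mean QALY from
  normal distributions with supplied means/SDs and an optional
  within-arm cost-effect correlation (used to reconstruct published
  summary-level analyses).

From the cloud: dominance-quadrant probabilities, willingness-to-pay
threshold probabilities, the acceptability curve (CEAC), the incremental
cost-effectiveness ratio when the trade-off quadrant applies, and the 95%
confidence ellipse.  Trials in the dominated quadrant count as exceeding
every willingness-to-pay threshold: an inferior strategy has no finite,
informative ICER.  In the southwest quadrant ranking is by net monetary
benefit, never by the (sign-flipped) raw ICER.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_N_TRIALS = 5000
#: willingness-to-pay grid, thousands of dollars per QALY
DEFAULT_WTP_GRID = tuple(float(x) for x in range(0, 1001, 10))


@dataclass
class PSACloud:
    """Per-trial incremental (cost $k, effect QALY) pairs."""
    delta_cost: np.ndarray    # $k
    delta_effect: np.ndarray  # QALYs
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.delta_cost = np.asarray(self.delta_cost, dtype=float)
        self.delta_effect = np.asarray(self.delta_effect, dtype=float)
        if self.delta_cost.shape != self.delta_effect.shape:
            raise ValueError("delta_cost and delta_effect must match in length")
        if self.delta_cost.size == 0:
            raise ValueError("empty PSA cloud")

    @property
    def n_trials(self) -> int:
        return int(self.delta_cost.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "trial": np.arange(self.n_trials),
            "delta_cost_k": self.delta_cost,
            "delta_effect_qaly": self.delta_effect,
        })


@dataclass
class IcerResult:
    """Point estimate on the cost-effectiveness plane."""
    mean_delta_cost: float    # $k
    mean_delta_effect: float  # QALYs
    classification: str       # dominant | dominated | tradeoff
    icer: Optional[float] = None  # $k per QALY, tradeoff only

    def __post_init__(self) -> None:
        if (self.icer is not None) != (self.classification == "tradeoff"):
            raise ValueError("ICER is reported exactly when classification "
                             "is 'tradeoff'")


@dataclass
class CEACurve:
    """Acceptance probability as a function of willingness-to-pay ($k/QALY)."""
    wtp: np.ndarray
    probability: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp_k_per_qaly": self.wtp,
                             "p_cost_effective": self.probability})


@dataclass
class Ellipse:
    """Confidence ellipse on the cost-effectiveness plane."""
    center: tuple[float, float]       # (delta_effect, delta_cost)
    semi_axes: tuple[float, float]    # major, minor
    orientation: float                # radians, major axis vs. effect axis
    level: float

    def contains(self, effect: np.ndarray, cost: np.ndarray) -> np.ndarray:
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        x = np.asarray(effect) - self.center[0]
        y = np.asarray(cost) - self.center[1]
        u = c * x + s * y
        v = -s * x + c * y
        a, b = self.semi_axes
        if a == 0 or b == 0:
            return (u == 0) & (v == 0)
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0


# ---------------------------------------------------------------------------
# per-patient preprocessing
# ---------------------------------------------------------------------------

def winsorize_p95(values: Sequence[float], percentile: float = 95.0) -> np.ndarray:
    """Replace values above the empirical 95th percentile by that percentile."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot winsorize an empty vector")
    cap = np.percentile(arr, percentile)
    return np.minimum(arr, cap)


def incremental(treatment_value: float, comparator_value: float) -> float:
    """Incremental quantity: treatment minus comparator."""
    return treatment_value - comparator_value


# ---------------------------------------------------------------------------
# Monte Carlo engines
# ---------------------------------------------------------------------------

def bootstrap_trial(cost_by_arm: dict[str, np.ndarray],
                    effect_by_arm: dict[str, np.ndarray],
                    rng: np.random.Generator,
                    winsorize_costs: bool = True) -> dict[str, tuple[float, float]]:
    """One bootstrap replicate: per-arm (mean cost $k, mean QALY).

    Patients are resampled with replacement within arm to the original arm
    size; costs are winsorized at the resample's 95th percentile before
    averaging.
    """
    out = {}
    for arm, costs in cost_by_arm.items():
        n = costs.size
        if n == 0:
            raise ValueError(f"arm {arm} is empty")
        idx = rng.integers(0, n, n)
        c = costs[idx]
        if winsorize_costs:
            c = winsorize_p95(c)
        out[arm] = (float(c.mean()) / 1e3, float(effect_by_arm[arm][idx].mean()))
    return out


def bootstrap_psa(results: pd.DataFrame, n_trials: int = DEFAULT_N_TRIALS,
                  seed: int = 0, treatment: str = "PAC", comparator: str = "CVC",
                  cost_col: str = "lifetime_cost", effect_col: str = "lifetime_qalys",
                  winsorize_costs: bool = True) -> PSACloud:
    """Nonparametric patient-level bootstrap PSA (vectorized over trials).

    ``results`` holds one row per patient with an ``arm`` column, lifetime
    cost in dollars and lifetime QALYs.  Returns the incremental cloud in
    $k and QALYs.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    means = {}
    for arm in (treatment, comparator):
        sub = results[results["arm"] == arm]
        if sub.empty:
            raise ValueError(f"arm {arm} is empty")
        costs = sub[cost_col].to_numpy(dtype=float)
        effects = sub[effect_col].to_numpy(dtype=float)
        n = costs.size
        idx = rng.integers(0, n, size=(n_trials, n))
        c = costs[idx]
        if winsorize_costs:
            cap = np.percentile(c, 95.0, axis=1, keepdims=True)
            c = np.minimum(c, cap)
        means[arm] = (c.mean(axis=1) / 1e3, effects[idx].mean(axis=1))
    dc = means[treatment][0] - means[comparator][0]
    de = means[treatment][1] - means[comparator][1]
    return PSACloud(delta_cost=dc, delta_effect=de, seed=seed)


@dataclass(frozen=True)
class ArmSummary:
    """Published arm-level summary: mean (SD) of lifetime cost and QALYs."""
    cost_mean_k: float
    cost_sd_k: float
    qaly_mean: float
    qaly_sd: float


def parametric_psa(treatment: ArmSummary, comparator: ArmSummary,
                   n_trials: int = DEFAULT_N_TRIALS, seed: int = 0,
                   correlation: float = 0.0) -> PSACloud:
    """Parametric PSA from arm-level normal summaries.

    Each trial draws every arm's mean cost and mean QALY from normal
    distributions; ``correlation`` couples cost and effect within arm
    (default 0 = independence).
    """
    if not -1.0 <= correlation <= 1.0:
        raise ValueError("correlation must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    draws = {}
    for name, arm in (("t", treatment), ("c", comparator)):
        cov = np.array([
            [arm.cost_sd_k ** 2, correlation * arm.cost_sd_k * arm.qaly_sd],
            [correlation * arm.cost_sd_k * arm.qaly_sd, arm.qaly_sd ** 2],
        ])
        sample = rng.multivariate_normal([arm.cost_mean_k, arm.qaly_mean],
                                         cov, size=n_trials)
        draws[name] = sample
    dc = draws["t"][:, 0] - draws["c"][:, 0]
    de = draws["t"][:, 1] - draws["c"][:, 1]
    return PSACloud(delta_cost=dc, delta_effect=de, seed=seed)


# ---------------------------------------------------------------------------
# summaries of the cloud
# ---------------------------------------------------------------------------

def icer_result(cloud: PSACloud) -> IcerResult:
    """Classify the mean of the cloud; report an ICER only for trade-offs."""
    dc = float(cloud.delta_cost.mean())
    de = float(cloud.delta_effect.mean())
    if dc <= 0 and de >= 0 and (dc < 0 or de > 0):
        return IcerResult(dc, de, "dominant")
    if dc >= 0 and de <= 0 and (dc > 0 or de < 0):
        return IcerResult(dc, de, "dominated")
    return IcerResult(dc, de, "tradeoff", icer=dc / de)


def quadrant_probs(cloud: PSACloud) -> dict[str, float]:
    """Probability mass in each cost-effectiveness-plane quadrant.

    Keys: ``dominated`` (costlier, less effective), ``dominant`` (cheaper,
    more effective), ``tradeoff_ne`` (costlier, more effective),
    ``tradeoff_sw`` (cheaper, less effective).  Boundary trials (a zero
    increment) split into the trade-off quadrants by the sign convention
    dc >= 0 -> NE, dc < 0 -> SW, so the four masses always sum to one.
    """
    dc, de = cloud.delta_cost, cloud.delta_effect
    n = cloud.n_trials
    n_dominated = int(np.sum((dc > 0) & (de < 0)))
    n_dominant = int(np.sum((dc < 0) & (de > 0)))
    n_ne = int(np.sum((dc >= 0) & (de >= 0)))
    n_sw = n - n_dominated - n_dominant - n_ne  # complement quadrant
    return {"dominated": n_dominated / n, "dominant": n_dominant / n,
            "tradeoff_ne": n_ne / n, "tradeoff_sw": n_sw / n}


def threshold_exceed_probs(cloud: PSACloud,
                           thresholds: Sequence[float]) -> dict[float, float]:
    """P(strategy exceeds each willingness-to-pay threshold, $k/QALY).

    A trial exceeds λ when its net monetary benefit λ·ΔE − ΔC is negative;
    dominated trials therefore exceed every threshold.
    """
    out = {}
    for lam in thresholds:
        nmb = lam * cloud.delta_effect - cloud.delta_cost
        out[float(lam)] = float(np.mean(nmb < 0))
    return out


def ceac(cloud: PSACloud,
         wtp_grid: Sequence[float] = DEFAULT_WTP_GRID) -> CEACurve:
    """Cost-effectiveness acceptability curve over a willingness-to-pay grid."""
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    probs = np.array([
        np.mean(lam * cloud.delta_effect - cloud.delta_cost >= 0)
        for lam in grid
    ])
    return CEACurve(wtp=grid, probability=probs)


def ceac_limit(cloud: PSACloud) -> float:
    """CEAC plateau as willingness-to-pay grows without bound.

    Equals P(ΔE > 0) plus the mass at ΔE = 0 with ΔC <= 0.
    """
    de, dc = cloud.delta_effect, cloud.delta_cost
    return float(np.mean((de > 0) | ((de == 0) & (dc <= 0))))


def confidence_ellipse(cloud: PSACloud, level: float = 0.95) -> Ellipse:
    """Confidence ellipse from the cloud's mean and covariance.

    Axes are scaled by the chi-square(2 df) quantile at ``level``; for a
    bivariate-normal cloud the fraction of points inside converges to the
    level.  Center and axes live on the (ΔE, ΔC) plane.
    """
    if cloud.n_trials < 3:
        raise ValueError("need at least 3 trials for an ellipse")
    if not 0.0 <= level < 1.0:
        raise ValueError("level must lie in [0, 1)")
    pts = np.column_stack([cloud.delta_effect, cloud.delta_cost])
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    if not np.all(np.isfinite(cov)) or np.linalg.matrix_rank(cov) < 2:
        raise ValueError("degenerate covariance: ellipse undefined")
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 0:
        raise ValueError("degenerate covariance: ellipse undefined")
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    q = stats.chi2.ppf(level, df=2) if level > 0 else 0.0
    semi = np.sqrt(evals * q)
    orientation = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return Ellipse(center=(float(center[0]), float(center[1])),
                   semi_axes=(float(semi[0]), float(semi[1])),
                   orientation=orientation, level=level)
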