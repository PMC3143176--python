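"""Calibration of the food-input coefficients against field targets.

Two modes, matching the two levels of field data a location may offer:

* **Per-type calibration** (productivity-rich sites): the type coefficients
  ``alpha_i`` (and location coefficients ``beta_j``, plus the overall scale
  ``F0``) are adjusted iteratively until the per-container-type share of
  total pupal production simulated by the model matches a target
  productivity distribution.  Updates are damped multiplicative ratios,
  ``alpha_i <- alpha_i * (target_i / simulated_i)^eta``, re-normalized every
  iteration so alpha(large tanks) = beta(outside) = 1 (the product form of
  the food equation makes scale and shape otherwise confounded).
* **F0-only calibration** (abundance-only sites): with alpha/beta frozen,
  a bracketed bisection scales ``F0`` until the simulated mean ovitrap
  positivity — the fraction of containers oviposited into within a trailing
  7-day window — matches the mean of an observed positivity series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .habitat import CONTAINER_TYPES, LOCATIONS, REFERENCE_LOCATION, REFERENCE_TYPE
from .simulator import BiologyParams, SimOutput, run_simulation

__all__ = [
    "ProductivityTable",
    "PositivitySeries",
    "CalibrationResult",
    "ovitrap_positivity",
    "calibrate_type_coefficients",
    "calibrate_overall_F0",
]

#: multiplicative trust region: per-iteration update ratios are clipped here
RATIO_CAP = 4.0


@dataclass(frozen=True)
class ProductivityTable:
    """Share of total pupal production per container type (a 14-simplex)."""

    share: dict[str, float]

    def __post_init__(self) -> None:
        unknown = set(self.share) - set(CONTAINER_TYPES)
        if unknown:
            raise ValueError(f"unknown container types: {sorted(unknown)}")
        vals = np.array([self.share.get(t, 0.0) for t in CONTAINER_TYPES])
        if (vals < 0).any():
            raise ValueError("shares must be >= 0")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"shares must sum to 1, got {vals.sum():.6g}")

    def as_array(self) -> np.ndarray:
        return np.array([self.share.get(t, 0.0) for t in CONTAINER_TYPES])

    @classmethod
    def from_array(cls, values) -> "ProductivityTable":
        values = np.asarray(values, dtype=float)
        return cls({t: float(v) for t, v in zip(CONTAINER_TYPES, values)})

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"type": list(CONTAINER_TYPES), "share": self.as_array()}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ProductivityTable":
        df = pd.read_csv(path)
        return cls(dict(zip(df["type"], df["share"].astype(float))))

    def restricted_to(self, types) -> "ProductivityTable":
        """Project the table onto a subset of types and renormalize.

        Used when a target distribution assigns mass to container types a
        particular grid does not hold.
        """
        keep = set(types)
        vals = np.array(
            [self.share.get(t, 0.0) if t in keep else 0.0 for t in CONTAINER_TYPES]
        )
        total = vals.sum()
        if total <= 0:
            raise ValueError("no target mass on the requested types")
        return ProductivityTable.from_array(vals / total)


@dataclass(frozen=True)
class PositivitySeries:
    """Fraction of positive traps/containers per time index (day or week)."""

    index: np.ndarray
    fraction: np.ndarray
    lo: np.ndarray | None = None
    hi: np.ndarray | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.fraction, dtype=float)
        if ((f < 0) | (f > 1)).any():
            raise ValueError("positivity fractions must lie in [0, 1]")
        object.__setattr__(self, "index", np.asarray(self.index))
        object.__setattr__(self, "fraction", f)

    @property
    def mean(self) -> float:
        return float(self.fraction.mean())

    def weekly(self) -> "PositivitySeries":
        """Aggregate a daily series to weekly means."""
        n = len(self.fraction) // 7
        f = self.fraction[: n * 7].reshape(n, 7).mean(axis=1)
        return PositivitySeries(np.arange(n), f)

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"week": self.index, "fraction": self.fraction})
        if self.lo is not None:
            df["lo"], df["hi"] = self.lo, self.hi
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PositivitySeries":
        df = pd.read_csv(path)
        return cls(
            df.iloc[:, 0].to_numpy(),
            df["fraction"].to_numpy(float),
            lo=df["lo"].to_numpy(float) if "lo" in df else None,
            hi=df["hi"].to_numpy(float) if "hi" in df else None,
        )


@dataclass
class CalibrationResult:
    F0: float
    alpha: dict[str, float]
    beta: dict[str, float]
    converged: bool
    n_iterations: int
    trace: list[float] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)

    def params(self, base: BiologyParams) -> BiologyParams:
        return base.with_food_coefficients(F0=self.F0, alpha=self.alpha,
                                           beta=self.beta)

    def to_json_dict(self) -> dict:
        return {
            "F0": self.F0,
            "alpha": self.alpha,
            "beta": self.beta,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "trace": self.trace,
            "seeds": self.seeds,
        }


def ovitrap_positivity(output: SimOutput, window: int = 7) -> PositivitySeries:
    """Daily fraction of containers oviposited into within the trailing window.

    The model's proxy for weekly ovitrap monitoring: a container counts as
    positive on day t if at least one oviposition event hit it on days
    ``t-window+1 .. t``.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    ind = output.ovi_indicator
    n_days, n_cont = ind.shape
    # sliding any-hit via cumulative sums of the 0/1 indicator
    c = np.cumsum(ind.astype(np.int32), axis=0)
    pad = np.vstack([np.zeros((1, n_cont), dtype=np.int32), c])
    start = np.maximum(0, np.arange(n_days) - window + 1)
    hits = pad[np.arange(n_days) + 1] - pad[start]
    frac = (hits > 0).mean(axis=1) if n_cont else np.zeros(n_days)
    return PositivitySeries(np.arange(n_days), frac)


def _simulated_shares(
    grid, weather, params, replicates, seeds, burn_in, horizon, inoculum=(10, 5)
) -> tuple[np.ndarray, float]:
    counts = np.zeros(len(CONTAINER_TYPES))
    for s in seeds[:replicates]:
        out = run_simulation(grid, weather, params, burn_in, int(s),
                             horizon=horizon, inoculum=inoculum)
        counts += out.per_type_pupae().to_numpy()
    total = counts.sum()
    shares = counts / total if total > 0 else counts
    return shares, total / replicates


def calibrate_type_coefficients(
    grid,
    weather,
    target: ProductivityTable,
    params0: BiologyParams,
    replicates: int = 5,
    tol: float = 0.02,
    max_iter: int = 20,
    eta: float = 0.5,
    seed: int = 0,
    burn_in_days: int = 365,
    horizon: int | None = None,
    target_total: float | None = None,
) -> CalibrationResult:
    """Fit alpha (and beta, F0) so simulated per-type shares match the target.

    Each iteration runs ``replicates`` seeded simulations, pools pupal
    production by container type, and applies damped multiplicative updates
    with ratios clipped to [1/4, 4] (so stochastic extinction of a rare type
    never produces a division blow-up).  After every update alpha and beta
    are re-normalized to the reference type/location, the removed scale being
    absorbed into F0.  ``target_total`` optionally calibrates F0 against a
    mean total pupal production; otherwise F0 keeps its normalized drift.
    Stops when max_i |simulated_i - target_i| <= tol.
    """
    t = target.as_array()
    present = np.zeros(len(CONTAINER_TYPES), dtype=bool)
    for h in grid.houses:
        for c in h.containers:
            present[c.type_index] = True
    absent_with_target = (~present) & (t > 0)
    if absent_with_target.any():
        bad = [CONTAINER_TYPES[i] for i in np.nonzero(absent_with_target)[0]]
        raise ValueError(f"target assigns share to types absent from grid: {bad}")

    alpha = np.array([params0.alpha[k] for k in CONTAINER_TYPES], dtype=float)
    beta = {k: float(v) for k, v in params0.beta.items()}
    F0 = params0.F0
    rng = np.random.default_rng(seed)
    all_seeds: list[int] = []
    trace: list[float] = []
    converged = False
    step = eta
    worse_streak = 0

    it = 0
    for it in range(1, max_iter + 1):
        seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=replicates)]
        all_seeds += seeds
        params = params0.with_food_coefficients(
            F0=F0, alpha=dict(zip(CONTAINER_TYPES, alpha)), beta=beta
        )
        sim, mean_total = _simulated_shares(
            grid, weather, params, replicates, seeds, burn_in_days, horizon
        )
        disc = float(np.max(np.abs(sim - t)))
        trace.append(disc)
        if disc <= tol:
            converged = True
            break
        if len(trace) >= 6 and all(
            trace[-k] > trace[-k - 1] for k in range(1, 6)
        ):
            step = max(step / 2.0, 0.05)  # persistent worsening: damp harder
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(sim > 0, t / np.maximum(sim, 1e-12), RATIO_CAP)
        ratio = np.where(t == 0, np.minimum(ratio, 1.0), ratio)
        ratio = np.clip(ratio, 1.0 / RATIO_CAP, RATIO_CAP)
        alpha = alpha * np.where(present, ratio**step, 1.0)
        # re-normalize: alpha(reference type) = 1, scale absorbed by F0
        ref = alpha[CONTAINER_TYPES.index(REFERENCE_TYPE)]
        alpha = alpha / ref
        F0 = F0 * ref
        if target_total is not None and mean_total > 0:
            F0 = F0 * np.clip(
                (target_total / mean_total) ** step, 1 / RATIO_CAP, RATIO_CAP
            )

    return CalibrationResult(
        F0=float(F0),
        alpha={k: float(v) for k, v in zip(CONTAINER_TYPES, alpha)},
        beta=beta,
        converged=converged,
        n_iterations=it,
        trace=trace,
        seeds=all_seeds,
    )


def calibrate_overall_F0(
    grid,
    weather,
    target: PositivitySeries,
    params0: BiologyParams,
    tol: float = 0.02,
    max_iter: int = 12,
    seed: int = 0,
    burn_in_days: int = 365,
    horizon: int | None = None,
    replicates: int = 1,
    window: int = 7,
) -> CalibrationResult:
    """Scalar search for F0 matching a target mean ovitrap positivity.

    alpha and beta stay frozen at their donor values.  Mean seasonal
    positivity is monotone in F0 over the bracket, so a log-scale bisection
    applies; the initial bracket [F0/4, 4*F0] is widened geometrically (up to
    two doublings each side) if it does not straddle the target.
    """
    target_mean = target.mean
    rng = np.random.default_rng(seed)
    seeds_used: list[int] = []
    trace: list[float] = []

    def positivity_at(f0: float) -> float:
        vals = []
        for _ in range(replicates):
            s = int(rng.integers(0, 2**31 - 1))
            seeds_used.append(s)
            out = run_simulation(
                grid, weather, params0.with_food_coefficients(F0=f0),
                burn_in_days, s, horizon=horizon,
            )
            vals.append(ovitrap_positivity(out, window=window).mean)
        return float(np.mean(vals))

    lo, hi = params0.F0 / 4.0, params0.F0 * 4.0
    f_lo, f_hi = positivity_at(lo), positivity_at(hi)
    widenings = 0
    while not (f_lo <= target_mean <= f_hi) and widenings < 2:
        lo, hi = lo / 4.0, hi * 4.0
        f_lo, f_hi = positivity_at(lo), positivity_at(hi)
        widenings += 1
    if not (f_lo - tol <= target_mean <= f_hi + tol):
        raise ValueError(
            f"target mean positivity {target_mean:.3f} outside achievable "
            f"range [{f_lo:.3f}, {f_hi:.3f}]"
        )

    best_f0, best_gap = params0.F0, np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mid = float(np.sqrt(lo * hi))
        f_mid = positivity_at(mid)
        gap = abs(f_mid - target_mean)
        trace.append(gap)
        if gap < best_gap:
            best_f0, best_gap = mid, gap
        if gap <= tol:
            converged = True
            break
        if f_mid < target_mean:
            lo = mid
        else:
            hi = mid

    return CalibrationResult(
        F0=float(best_f0),
        alpha=dict(params0.alpha),
        beta=dict(params0.beta),
        converged=converged,
        n_iterations=it,
        trace=trace,
        seeds=seeds_used,
    )
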