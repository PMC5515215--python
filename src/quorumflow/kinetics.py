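"""AHL inactivation kinetics from spiked time-course data.

Sludge microcosms are spiked with synthetic AHLs (typically 5 uM each)
and residual concentrations are followed over time in three conditions:
live sludge, heat-inactivated sludge and a synthetic-wastewater (SWW)
control. The instantaneous concentration drop shared by the live and
heat-inactivated series measures adsorption to biomass; the additional
decay in the live series is attributed to enzymatic quorum quenching.

Half-lives are estimated under zero-order kinetics
(C(t) = C0 - k t, t1/2 = C0 / (2 k)) or first-order kinetics
(C(t) = C0 exp(-k t), t1/2 = ln 2 / k), with the better-fitting order
selected per series. Replicate half-lives are compared between
conditions with Welch t-tests under Holm-Sidak multiple-comparison
adjustment, and the dependence of half-life on acyl chain length is
summarised with Spearman rank correlation per C3-substitution class.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from ._ahl import AHL, parse_acronym

logger = logging.getLogger(__name__)

CONDITIONS = ("live", "heat_inactivated", "sww_control")

LN2 = float(np.log(2.0))


@dataclass
class DecaySeries:
    """A spiked time course for one AHL under one condition.

    times are hours (ascending, starting at 0); concentrations are uM
    and nonnegative. ``ph_range`` records the bulk-liquid pH window.
    """

    ahl: str
    condition: str
    times: np.ndarray
    concentrations: np.ndarray
    ph_range: tuple[float, float] = (6.7, 6.9)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.times.ndim != 1 or self.times.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must be 1-d and equal length")
        if len(self.times) and self.times[0] != 0:
            raise ValueError("time course must start at t=0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be nonnegative")


@dataclass
class KineticFit:
    """Result of a zero- or first-order fit.

    ``ok`` is False for degenerate/non-degrading series; ``reason``
    explains why. Invariants: order 0 => half_life = c0_hat/(2 rate_k);
    order 1 => half_life = ln2/rate_k.
    """

    order: int
    c0_hat: float = float("nan")
    rate_k: float = float("nan")
    half_life: float = float("nan")
    half_life_se: float = float("nan")
    r_squared: float = float("nan")
    ok: bool = True
    reason: str | None = None


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 0.0
    return max(0.0, 1.0 - ss_res / ss_tot)


class ZeroOrderDecayFitter(BaseEstimator):
    """Zero-order (linear) decay model C(t) = c0 - k t fitted by OLS.

    Fitted attributes: ``c0_``, ``rate_k_``, ``half_life_``,
    ``half_life_se_``, ``r_squared_``, ``result_``.
    """

    order = 0

    def fit(self, t: Sequence[float], c: Sequence[float]) -> "ZeroOrderDecayFitter":
        t = np.asarray(t, dtype=float)
        c = np.asarray(c, dtype=float)
        self.result_ = self._fit(t, c)
        self.c0_ = self.result_.c0_hat
        self.rate_k_ = self.result_.rate_k
        self.half_life_ = self.result_.half_life
        self.half_life_se_ = self.result_.half_life_se
        self.r_squared_ = self.result_.r_squared
        return self

    def _fit(self, t: np.ndarray, c: np.ndarray) -> KineticFit:
        if len(t) < 3:
            return KineticFit(order=0, ok=False, reason="fewer than 3 timepoints")
        if np.allclose(c, c[0]):
            return KineticFit(order=0, ok=False, reason="constant concentrations")
        res = stats.linregress(t, c)
        c0, slope = float(res.intercept), float(res.slope)
        k = -slope
        r2 = _r_squared(c, c0 + slope * t)
        if k <= 0:
            return KineticFit(order=0, c0_hat=c0, rate_k=k, r_squared=r2,
                              ok=False, reason="non-degrading (slope >= 0)")
        half_life = c0 / (2.0 * k)
        # delta method on t1/2 = c0 / (2k) with OLS covariance of (intercept, slope)
        n = len(t)
        resid = c - (c0 + slope * t)
        s2 = float(np.sum(resid**2)) / max(n - 2, 1)
        sxx = float(np.sum((t - t.mean()) ** 2))
        var_slope = s2 / sxx
        var_int = s2 * (1.0 / n + t.mean() ** 2 / sxx)
        cov_is = -s2 * t.mean() / sxx
        d_c0 = 1.0 / (2.0 * k)
        d_k = -c0 / (2.0 * k**2)  # dk = -dslope
        var_hl = (
            d_c0**2 * var_int + d_k**2 * var_slope + 2.0 * d_c0 * (-d_k) * cov_is
        )
        se = float(np.sqrt(max(var_hl, 0.0)))
        return KineticFit(order=0, c0_hat=c0, rate_k=k, half_life=half_life,
                          half_life_se=se, r_squared=r2)

    def predict(self, t: Sequence[float]) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.c0_ - self.rate_k_ * t


class FirstOrderDecayFitter(BaseEstimator):
    """First-order (exponential) decay C(t) = c0 exp(-k t).

    The default fit is log-linear least squares of ln C on t, optionally
    refined by a nonlinear least-squares pass minimising the SSE on the
    concentration scale. Zero concentrations are floored at
    ``zero_floor`` (conventionally LOQ/2) before the log transform; if
    the all-zero tail exceeds half the series the fit is abandoned.

    Parameters
    ----------
    refine : bool
        Run the nonlinear SSE refinement after the log-linear fit.
    zero_floor : float or None
        Replacement for zero concentrations before the log transform.
        None floors at half the smallest positive observation.
    """

    order = 1

    def __init__(self, refine: bool = True, zero_floor: float | None = None):
        self.refine = refine
        self.zero_floor = zero_floor

    def fit(self, t: Sequence[float], c: Sequence[float]) -> "FirstOrderDecayFitter":
        t = np.asarray(t, dtype=float)
        c = np.asarray(c, dtype=float)
        self.result_ = self._fit(t, c)
        self.c0_ = self.result_.c0_hat
        self.rate_k_ = self.result_.rate_k
        self.half_life_ = self.result_.half_life
        self.half_life_se_ = self.result_.half_life_se
        self.r_squared_ = self.result_.r_squared
        return self

    def _fit(self, t: np.ndarray, c: np.ndarray) -> KineticFit:
        if len(t) < 3:
            return KineticFit(order=1, ok=False, reason="fewer than 3 timepoints")
        if np.allclose(c, c[0]):
            return KineticFit(order=1, ok=False, reason="constant concentrations")
        n_zero_tail = 0
        for v in c[::-1]:
            if v > 0:
                break
            n_zero_tail += 1
        if n_zero_tail > len(c) / 2:
            return KineticFit(order=1, ok=False,
                              reason="all-zero tail longer than half the series")
        c_use = c.copy()
        if np.any(c_use <= 0):
            floor = self.zero_floor
            if floor is None:
                positive = c_use[c_use > 0]
                floor = float(positive.min()) / 2.0
            c_use = np.where(c_use <= 0, floor, c_use)
        logc = np.log(c_use)
        res = stats.linregress(t, logc)
        k = -float(res.slope)
        c0 = float(np.exp(res.intercept))
        if self.refine and k > 0:
            try:
                popt, pcov = optimize.curve_fit(
                    lambda tt, c0_, k_: c0_ * np.exp(-k_ * tt),
                    t, c, p0=[c0, k], maxfev=10000,
                )
                if popt[1] > 0:
                    c0, k = float(popt[0]), float(popt[1])
                    se_k = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else float("nan")
                else:
                    se_k = float(res.stderr)
            except RuntimeError:
                se_k = float(res.stderr)
        else:
            se_k = float(res.stderr)
        r2 = _r_squared(c, c0 * np.exp(-k * t))
        if k <= 0:
            return KineticFit(order=1, c0_hat=c0, rate_k=k, r_squared=r2,
                              ok=False, reason="non-degrading (slope >= 0)")
        half_life = LN2 / k
        se = LN2 / k**2 * se_k if np.isfinite(se_k) else float("nan")
        return KineticFit(order=1, c0_hat=c0, rate_k=k, half_life=half_life,
                          half_life_se=se, r_squared=r2)

    def predict(self, t: Sequence[float]) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.c0_ * np.exp(-self.rate_k_ * t)


def fit_zero_order(series: DecaySeries) -> KineticFit:
    """OLS of concentration on time; half-life C0/(2k)."""
    return ZeroOrderDecayFitter().fit(series.times, series.concentrations).result_


def fit_first_order(series: DecaySeries, refine: bool = True,
                    zero_floor: float | None = None) -> KineticFit:
    """Log-linear least squares (with nonlinear refinement); half-life ln2/k."""
    fitter = FirstOrderDecayFitter(refine=refine, zero_floor=zero_floor)
    return fitter.fit(series.times, series.concentrations).result_


def select_model(fit_zero: KineticFit, fit_first: KineticFit,
                 tie_tol: float = 1e-6) -> KineticFit:
    """Pick the order with the higher r-squared; ties go to first-order."""
    if not fit_zero.ok and not fit_first.ok:
        return KineticFit(order=1, ok=False, reason="both fits failed")
    if not fit_zero.ok:
        return fit_first
    if not fit_first.ok:
        return fit_zero
    if fit_zero.r_squared > fit_first.r_squared + tie_tol:
        return fit_zero
    return fit_first


def adsorption_fraction(sww: DecaySeries, heat: DecaySeries,
                        window_h: float = 0.25) -> tuple[float, tuple[float, float]]:
    """Fraction of signal lost to biomass adsorption.

    Compares the SWW and heat-inactivated controls immediately after
    addition (t=0) and after 1 h:
    fraction = 1 - mean(heat at {0, 1h}) / mean(sww at {0, 1h}),
    clamped to [0, 1]. Returns (fraction, (per-timepoint estimates)).
    """
    def _pick(series: DecaySeries, target: float) -> float:
        idx = int(np.argmin(np.abs(series.times - target)))
        if abs(series.times[idx] - target) > window_h:
            raise ValueError(
                f"{series.condition}: no timepoint within {window_h} h of t={target}"
            )
        return float(series.concentrations[idx])

    sww_vals = np.array([_pick(sww, 0.0), _pick(sww, 1.0)])
    heat_vals = np.array([_pick(heat, 0.0), _pick(heat, 1.0)])
    if np.mean(sww_vals) <= 0:
        raise ValueError("SWW control concentrations are zero; cannot estimate adsorption")
    raw = 1.0 - float(np.mean(heat_vals)) / float(np.mean(sww_vals))
    per_point = tuple(
        float(np.clip(1.0 - h / s, 0.0, 1.0)) if s > 0 else float("nan")
        for h, s in zip(heat_vals, sww_vals)
    )
    if raw < 0:
        warnings.warn("heat-inactivated control above SWW control; adsorption clamped to 0")
    return float(np.clip(raw, 0.0, 1.0)), per_point


def correct_for_adsorption(series: DecaySeries, fraction: float) -> DecaySeries:
    """Rescale a live series by 1/(1 - fraction) to isolate enzymatic decay.

    All measured points are rescaled: the t=0 sample is collected
    immediately after addition and already reflects the instantaneous
    adsorption drop.
    """
    if not 0 <= fraction < 1:
        raise ValueError("adsorption fraction must be in [0, 1)")
    return DecaySeries(
        ahl=series.ahl,
        condition=series.condition,
        times=series.times.copy(),
        concentrations=series.concentrations / (1.0 - fraction),
        ph_range=series.ph_range,
    )


def holm_sidak_adjust(p_raw: Sequence[float]) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values (via statsmodels)."""
    p_raw = np.asarray(p_raw, dtype=float)
    if len(p_raw) == 0:
        return p_raw
    return multipletests(p_raw, method="holm-sidak")[1]


def compare_half_lives(
    group_a: Mapping[str, Sequence[float]],
    group_b: Mapping[str, Sequence[float]],
    labels: tuple[str, str] = ("live", "heat_inactivated"),
) -> pd.DataFrame:
    """Per-AHL Welch t-tests on replicate half-lives, Holm-Sidak adjusted.

    AHLs with fewer than 2 replicates in either group are excluded (with
    a logged notice). Returns a DataFrame with columns
    ahl, n_a, n_b, mean_a, mean_b, t_stat, p_raw, p_adj.
    """
    rows = []
    for ahl in group_a:
        if ahl not in group_b:
            logger.info("AHL %s absent from group %s; skipped", ahl, labels[1])
            continue
        a = np.asarray(group_a[ahl], dtype=float)
        b = np.asarray(group_b[ahl], dtype=float)
        if len(a) < 2 or len(b) < 2:
            logger.info("AHL %s has <2 replicates in a group; excluded", ahl)
            continue
        t_stat, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({"ahl": ahl, "n_a": len(a), "n_b": len(b),
                     "mean_a": float(a.mean()), "mean_b": float(b.mean()),
                     "t_stat": float(t_stat), "p_raw": float(p)})
    df = pd.DataFrame(rows, columns=["ahl", "n_a", "n_b", "mean_a", "mean_b",
                                     "t_stat", "p_raw"])
    if len(df):
        df["p_adj"] = holm_sidak_adjust(df["p_raw"].to_numpy())
    else:
        df["p_adj"] = []
    return df


def chain_length_trend(half_lives: Mapping[str, float]) -> pd.DataFrame:
    """Spearman rank correlation of half-life vs acyl chain length per substitution class.

    A negative correlation flags the inverse half-life/chain-length
    trend (longer acyl chains degraded faster). Classes with fewer than
    3 AHLs are reported with NaN correlation; all-tied half-lives leave
    the correlation undefined.
    """
    records: dict[str, list[tuple[AHL, float]]] = {}
    for acronym, hl in half_lives.items():
        ahl = parse_acronym(acronym)
        records.setdefault(ahl.substitution, []).append((ahl, float(hl)))
    rows = []
    for substitution, items in sorted(records.items()):
        chains = np.array([a.chain_length for a, _ in items], dtype=float)
        hls = np.array([hl for _, hl in items], dtype=float)
        if len(items) < 3:
            rows.append({"substitution": substitution, "n_ahls": len(items),
                         "spearman_rho": float("nan"), "inverse_trend": False,
                         "note": "fewer than 3 AHLs"})
            continue
        if np.all(hls == hls[0]):
            rows.append({"substitution": substitution, "n_ahls": len(items),
                         "spearman_rho": float("nan"), "inverse_trend": False,
                         "note": "all half-lives tied; correlation undefined"})
            continue
        rho = float(stats.spearmanr(chains, hls).statistic)
        rows.append({"substitution": substitution, "n_ahls": len(items),
                     "spearman_rho": rho, "inverse_trend": rho < 0, "note": ""})
    return pd.DataFrame(rows, columns=["substitution", "n_ahls", "spearman_rho",
                                       "inverse_trend", "note"])


@dataclass
class KineticsReport:
    """Per-AHL selected fits plus adsorption and comparison summaries."""

    fits: pd.DataFrame
    comparisons: pd.DataFrame | None = None
    trend: pd.DataFrame | None = None
    adsorption: dict[str, float] = field(default_factory=dict)


def analyse_decay_table(
    table: pd.DataFrame,
    correct_adsorption: bool = True,
    per_replicate: bool = True,
) -> KineticsReport:
    """Full kinetics analysis of a long-format decay table.

    Expected columns: ahl, condition, replicate, time_h, concentration.
    For each AHL: adsorption fraction from the two controls, zero- and
    first-order fits of each live replicate (adsorption-corrected by
    default), model selection, half-life comparison live vs
    heat-inactivated, and the chain-length trend over selected fits.
    With ``per_replicate`` False, replicates are pooled by mean at each
    timepoint before fitting.
    """
    required = {"ahl", "condition", "replicate", "time_h", "concentration"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"decay table missing columns: {sorted(missing)}")

    def _series(sub: pd.DataFrame, ahl: str, condition: str) -> DecaySeries:
        g = sub.groupby("time_h", as_index=False)["concentration"].mean()
        return DecaySeries(ahl=ahl, condition=condition,
                           times=g["time_h"].to_numpy(),
                           concentrations=g["concentration"].to_numpy())

    fit_rows = []
    adsorption: dict[str, float] = {}
    live_hl: dict[str, list[float]] = {}
    heat_hl: dict[str, list[float]] = {}
    for ahl, sub in table.groupby("ahl"):
        by_cond = {c: g for c, g in sub.groupby("condition")}
        frac = 0.0
        if "sww_control" in by_cond and "heat_inactivated" in by_cond:
            try:
                frac, _ = adsorption_fraction(
                    _series(by_cond["sww_control"], ahl, "sww_control"),
                    _series(by_cond["heat_inactivated"], ahl, "heat_inactivated"),
                )
            except ValueError as exc:
                logger.warning("AHL %s: adsorption estimate failed (%s)", ahl, exc)
        adsorption[ahl] = frac

        for condition in ("live", "heat_inactivated"):
            if condition not in by_cond:
                continue
            cond_df = by_cond[condition]
            groups = (
                [(r, g) for r, g in cond_df.groupby("replicate")]
                if per_replicate else [("pooled", cond_df)]
            )
            for replicate, g in groups:
                series = _series(g, ahl, condition)
                if condition == "live" and correct_adsorption and 0 < frac < 1:
                    series = correct_for_adsorption(series, frac)
                fit = select_model(fit_zero_order(series), fit_first_order(series))
                fit_rows.append({
                    "ahl": ahl, "condition": condition, "replicate": replicate,
                    "order": fit.order, "rate_k": fit.rate_k,
                    "half_life": fit.half_life, "half_life_se": fit.half_life_se,
                    "r_squared": fit.r_squared,
                    "adsorption_fraction": frac, "ok": fit.ok,
                    "reason": fit.reason or "",
                })
                if fit.ok:
                    target = live_hl if condition == "live" else heat_hl
                    target.setdefault(ahl, []).append(fit.half_life)

    fits = pd.DataFrame(fit_rows)
    comparisons = compare_half_lives(live_hl, heat_hl) if live_hl and heat_hl else None
    mean_live = {a: float(np.mean(v)) for a, v in live_hl.items()}
    trend = chain_length_trend(mean_live) if mean_live else None
    return KineticsReport(fits=fits, comparisons=comparisons, trend=trend,
                          adsorption=adsorption)
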