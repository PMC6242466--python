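"""Per-day regularized t-testing and multi-day hit calling.

With only a handful of replicates per strain, per-strain sample variances
are unstable. The regularized (empirical-Bayes) t-test shrinks each
strain's variance toward a background variance estimated from strains of
similar mean density: strains are ranked by their mean normalized density
and the background variance is the average sample variance over a window
of ranked neighbors. The posterior variance

    sigma~^2 = (conf * sigma0^2 + (n - 1) * s^2) / (conf + n - 2)

weights the background by ``conf`` pseudo-observations (default 15, so the
neighbors dominate with n = 4 replicates). The t statistic uses the
Welch-style pooled standard error and, by default,
``df = n_c + n_d + 2 * conf - 4`` (each group carries ``n + conf - 2``
effective degrees of freedom); plain ``n_c + n_d - 2`` is available.

P-values are Benjamini-Hochberg adjusted per day; a strain is a hit when
its adjusted p-value falls below ``alpha`` on at least ``min_days`` days
with a consistent sign of the drug - control difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import DensityTable


@dataclass
class TestParams:
    __test__ = False  # not a pytest collection target

    conf: float = 15.0
    window: int = 101
    alpha: float = 0.01
    min_days: int = 2
    df_convention: str = "regularized"  # or "classic"
    adjusted_threshold: bool = True  # threshold BH-adjusted p (else raw)

    def __post_init__(self) -> None:
        if self.conf < 0:
            raise ValueError("conf must be >= 0")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_days < 1:
            raise ValueError("min_days must be >= 1")
        if self.df_convention not in ("regularized", "classic"):
            raise ValueError("df_convention must be 'regularized' or 'classic'")


def window_background_variance(
    means: np.ndarray, variances: np.ndarray, window: int
) -> np.ndarray:
    """Mean sample variance over a rank window centered on each strain.

    Strains are ranked by ``means``; each strain's background variance is
    the mean of the sample variances of the ``window`` strains centered on
    it in rank order, truncating the window at the ends. Returned in the
    input (unranked) order.
    """
    means = np.asarray(means, dtype=float)
    variances = np.asarray(variances, dtype=float)
    n = means.size
    if variances.size != n:
        raise ValueError("means and variances must have equal length")
    if window > n:
        warnings.warn(f"window {window} > {n} strains; clamping")
        window = n
    if window >= n:  # the window spans every strain regardless of centering
        return np.full(n, variances.mean())
    half = window // 2
    order = np.argsort(means, kind="stable")
    ranked_var = variances[order]
    csum = np.concatenate([[0.0], np.cumsum(ranked_var)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    bg_ranked = (csum[hi] - csum[lo]) / (hi - lo)
    bg = np.empty(n)
    bg[order] = bg_ranked
    return bg


def regularized_variance(s2, n, sigma0_sq, conf: float):
    """Posterior variance: (conf * sigma0^2 + (n - 1) * s^2) / (conf + n - 2)."""
    s2 = np.asarray(s2, dtype=float)
    n = np.asarray(n, dtype=float)
    sigma0_sq = np.asarray(sigma0_sq, dtype=float)
    return (conf * sigma0_sq + (n - 1.0) * s2) / (conf + n - 2.0)


def regularized_t(
    control: np.ndarray,
    drug: np.ndarray,
    sigma0_sq_control,
    sigma0_sq_drug,
    conf: float = 15.0,
    df_convention: str = "regularized",
):
    """Regularized two-sample t-test on replicate value matrices.

    ``control`` and ``drug`` are (n_strains, n_replicates) arrays (NaN for
    missing replicates). Returns ``(t, df, p_two_sided, delta)`` arrays;
    strains with fewer than 2 replicates in either group get t = 0, p = 1.
    """
    control = np.atleast_2d(np.asarray(control, dtype=float))
    drug = np.atleast_2d(np.asarray(drug, dtype=float))
    n_c = np.isfinite(control).sum(axis=1)
    n_d = np.isfinite(drug).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_c = np.nanmean(control, axis=1)
        mean_d = np.nanmean(drug, axis=1)
        s2_c = np.nanvar(control, axis=1, ddof=1)
        s2_d = np.nanvar(drug, axis=1, ddof=1)
    delta = mean_d - mean_c

    var_c = regularized_variance(s2_c, n_c, sigma0_sq_control, conf)
    var_d = regularized_variance(s2_d, n_d, sigma0_sq_drug, conf)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(var_c / n_c + var_d / n_d)
        t = delta / se
    if df_convention == "regularized":
        df = n_c + n_d + 2.0 * conf - 4.0
    else:
        df = n_c + n_d - 2.0

    enough = (n_c >= 2) & (n_d >= 2)
    degenerate = enough & (se == 0)  # zero regularized variance in both groups
    valid = enough & np.isfinite(t)
    t = np.where(valid, t, 0.0)
    p = np.ones_like(t)
    p[valid] = 2.0 * stats.t.sf(np.abs(t[valid]), df[valid])
    p[degenerate & (delta != 0)] = 0.0  # exact difference with no variance
    t[degenerate & (delta != 0)] = np.sign(delta[degenerate & (delta != 0)]) * np.inf
    p = np.clip(p, 0.0, 1.0)
    return t, df, p, delta


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN passed through)."""
    p = np.asarray(p_values, dtype=float)
    if np.nanmin(p, initial=0.0) < 0 or np.nanmax(p, initial=0.0) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def day_test(
    table: DensityTable,
    day,
    params: TestParams | None = None,
    control: str = "control",
    drug: str = "drug",
) -> pd.DataFrame:
    """Run the regularized test for one day of a normalized table.

    Strains missing more than one replicate in either condition are
    excluded from the day's test. Returns a per-strain frame with means,
    variances, background and regularized variances, t, df, raw and
    BH-adjusted p, and the direction of the drug - control difference.
    """
    if params is None:
        params = TestParams()
    if table.stage == "raw":
        raise ValueError("test expects log-scale (normalized) values")
    ctrl = table.pivot(control, day)
    drg = table.pivot(drug, day)
    strains = ctrl.index.intersection(drg.index)
    ctrl, drg = ctrl.loc[strains], drg.loc[strains]

    n_rep_c = ctrl.shape[1]
    n_rep_d = drg.shape[1]
    ok = (ctrl.notna().sum(axis=1) >= max(2, n_rep_c - 1)) & (
        drg.notna().sum(axis=1) >= max(2, n_rep_d - 1)
    )
    ctrl, drg = ctrl.loc[ok], drg.loc[ok]
    strains = ctrl.index

    c = ctrl.to_numpy(dtype=float)
    d = drg.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_c, mean_d = np.nanmean(c, axis=1), np.nanmean(d, axis=1)
        s2_c = np.nanvar(c, axis=1, ddof=1)
        s2_d = np.nanvar(d, axis=1, ddof=1)
    window = min(params.window, len(strains) if len(strains) % 2 else len(strains) - 1)
    sigma0_c = window_background_variance(mean_c, s2_c, window)
    sigma0_d = window_background_variance(mean_d, s2_d, window)

    t, df, p, delta = regularized_t(
        c, d, sigma0_c, sigma0_d, conf=params.conf, df_convention=params.df_convention
    )
    res = pd.DataFrame(
        {
            "strain_id": strains,
            "day": day,
            "mean_control": mean_c,
            "mean_drug": mean_d,
            "delta": delta,
            "s2_control": s2_c,
            "s2_drug": s2_d,
            "sigma0_sq_control": sigma0_c,
            "sigma0_sq_drug": sigma0_d,
            "t": t,
            "df": df,
            "p_raw": p,
        }
    )
    res["p_adj"] = bh_adjust(res["p_raw"].to_numpy())
    res["direction"] = np.where(delta > 0, "+", np.where(delta < 0, "-", "0"))
    return res.reset_index(drop=True)


def test_all_days(table: DensityTable, params: TestParams | None = None,
                  **kw) -> pd.DataFrame:
    """Concatenated :func:`day_test` results over every day of the table."""
    return pd.concat(
        [day_test(table, day, params, **kw) for day in table.days],
        ignore_index=True,
    )


def call_hits(day_results: pd.DataFrame, params: TestParams | None = None) -> pd.DataFrame:
    """Combine per-day results into the multi-day hit table.

    A strain qualifies on a day when its (BH-adjusted, by default) p-value
    is below ``alpha``; it is a hit when at least ``min_days`` qualifying
    days agree in direction. Equal counts of qualifying days in both
    directions leave the strain uncalled, so the increased-on-drug and
    decreased-on-drug hit sets are disjoint by construction.
    """
    if params is None:
        params = TestParams()
    pcol = "p_adj" if params.adjusted_threshold else "p_raw"
    need = {"strain_id", "day", pcol, "delta"}
    if not need.issubset(day_results.columns):
        raise ValueError(f"day results must have columns {sorted(need)}")

    rows = []
    for strain, g in day_results.groupby("strain_id", sort=True):
        qual = g[(g[pcol] < params.alpha) & (g["delta"] != 0)]
        n_pos = int((qual["delta"] > 0).sum())
        n_neg = int((qual["delta"] < 0).sum())
        if n_pos >= params.min_days and n_pos > n_neg:
            is_hit, direction, n_sig = True, "+", n_pos
            days = sorted(qual.loc[qual["delta"] > 0, "day"])
        elif n_neg >= params.min_days and n_neg > n_pos:
            is_hit, direction, n_sig = True, "-", n_neg
            days = sorted(qual.loc[qual["delta"] < 0, "day"])
        else:
            is_hit, direction, n_sig = False, "0", max(n_pos, n_neg)
            days = sorted(qual["day"])
        rows.append(
            {
                "strain_id": strain,
                "qualifying_days": ",".join(str(d) for d in days),
                "n_days_significant": n_sig,
                "is_hit": is_hit,
                "direction": direction,
            }
        )
    return pd.DataFrame(rows)


def hit_sets(hits: pd.DataFrame) -> tuple[set, set]:
    """(increased on drug, decreased on drug) strain-ID sets."""
    up = set(hits.loc[hits["is_hit"] & (hits["direction"] == "+"), "strain_id"])
    down = set(hits.loc[hits["is_hit"] & (hits["direction"] == "-"), "strain_id"])
    return up, down
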