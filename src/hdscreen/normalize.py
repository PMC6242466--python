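"""Density transforms and normalization.

Three stages, applied in order:

1. ``log_transform`` — log2 of raw integrated densities (plus an optional
   pseudocount).
2. ``quantile_normalize`` — within each condition (and day), the replicate
   plate columns are forced onto a common distribution by replacing each
   value with the mean across columns of the values at its rank. Removes
   plate-to-plate technical variability.
3. ``cyclic_loess`` — for matched plate pairs (by default the control and
   drug plates of the same replicate), a local regression of the difference
   M = x_i - x_j on the average A = (x_i + x_j) / 2 estimates the
   colony-size-dependent basal effect of the drug on growth, which is then
   split antisymmetrically between the two columns. Cycling repeats until
   the summed absolute correction of a cycle drops below ``epsilon`` or
   ``maxit`` cycles have run.

The local regression is degree-1 with tricube weights and two robustness
(symmetric-family) re-weighting iterations, matching the robust local
regression family the correction is usually run with; the bandwidth
``span`` is the fraction of points in each window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

from .tables import DensityTable


@dataclass
class LoessParams:
    """Tuning of the cyclic LOESS stage."""

    span: float = 0.05
    epsilon: float = 1.0
    maxit: int = 5
    log_input: bool = False  # inputs are already on the log2 scale
    robust_iterations: int = 2  # symmetric-family re-weighting passes

    def __post_init__(self) -> None:
        if not 0.0 < self.span <= 1.0:
            raise ValueError("span must lie in (0, 1]")
        if self.maxit < 1:
            raise ValueError("maxit must be >= 1")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.robust_iterations < 0:
            raise ValueError("robust_iterations must be >= 0")


def log_transform(table: DensityTable, pseudocount: float = 1.0) -> DensityTable:
    """log2(value + pseudocount); moves the table to the ``logged`` stage."""
    if table.stage != "raw":
        raise ValueError(f"expected a raw-stage table, got {table.stage!r}")
    vals = table.data["value"]
    if (vals.dropna() < 0).any():
        raise ValueError("negative densities cannot be log-transformed")
    out = table.data.copy()
    out["value"] = np.log2(vals + pseudocount)
    return DensityTable(out, stage="logged")


def quantile_normalize(columns: pd.DataFrame) -> pd.DataFrame:
    """Force the columns of a value matrix onto their common distribution.

    Each column's value at rank r becomes the across-column mean of the
    rank-r values; ties receive the mean of their tied-rank targets, and
    missing values are excluded from ranking and restored as missing.
    Within-column rank order is preserved. With fewer than two columns the
    input is returned unchanged (with a warning).
    """
    df = pd.DataFrame(columns).copy()
    if df.shape[1] < 2:
        warnings.warn("quantile normalization needs >= 2 columns; returning input")
        return df
    counts = df.notna().sum(axis=0)
    if (counts < 2).any():
        raise ValueError("every column needs at least 2 non-missing values")

    m = int(counts.max())
    grid = np.linspace(0.0, 1.0, m)
    interpolated = np.empty((m, df.shape[1]))
    for j, col in enumerate(df.columns):
        v = np.sort(df[col].dropna().to_numpy(dtype=float))
        p = np.linspace(0.0, 1.0, v.size)
        interpolated[:, j] = np.interp(grid, p, v)
    reference = interpolated.mean(axis=1)

    out = df.copy()
    for col in df.columns:
        mask = df[col].notna().to_numpy()
        v = df[col].to_numpy(dtype=float)[mask]
        ranks = rankdata(v, method="average")  # 1..n, ties averaged
        p = (ranks - 1.0) / max(v.size - 1.0, 1.0)
        out.loc[mask, col] = np.interp(p, grid, reference)
    return out


def cyclic_loess(
    columns: pd.DataFrame,
    pairs: list[tuple],
    params: LoessParams | None = None,
) -> pd.DataFrame:
    """Cyclic pairwise M-vs-A local-regression normalization.

    ``columns`` is a strain x column value matrix (log2 scale);
    ``pairs`` lists column-label pairs to correct against each other.
    For each pair the fitted M trend is split half-and-half between the two
    columns (scaled by the number of pairs each column participates in), so
    the per-pair grand mean of A is preserved. Degenerate pairs with
    constant A are skipped with a warning.
    """
    if params is None:
        params = LoessParams()
    out = pd.DataFrame(columns).astype(float).copy()
    if params.log_input:
        out = np.log2(out)
    for a, b in pairs:
        if a not in out.columns or b not in out.columns:
            raise KeyError(f"pair ({a!r}, {b!r}) not in columns")

    n_pairs = {c: 0 for c in out.columns}
    for a, b in pairs:
        n_pairs[a] += 1
        n_pairs[b] += 1

    for _ in range(params.maxit):
        corrections = pd.DataFrame(0.0, index=out.index, columns=out.columns)
        for a, b in pairs:
            xa, xb = out[a].to_numpy(), out[b].to_numpy()
            mask = np.isfinite(xa) & np.isfinite(xb)
            A = (xa[mask] + xb[mask]) / 2.0
            M = xa[mask] - xb[mask]
            if A.size < 10 or np.ptp(A) < 1e-12:
                warnings.warn(f"skipping degenerate pair ({a!r}, {b!r})")
                continue
            fit = lowess(M, A, frac=params.span, it=params.robust_iterations,
                         return_sorted=False)
            half = fit / 2.0
            corrections.loc[mask, a] -= half / n_pairs[a]
            corrections.loc[mask, b] += half / n_pairs[b]
        out = out + corrections
        if np.abs(corrections.to_numpy()).sum() < params.epsilon:
            break
    return out


def normalize_table(
    table: DensityTable,
    pseudocount: float = 1.0,
    params: LoessParams | None = None,
    quantile: bool = True,
    loess: bool = True,
) -> DensityTable:
    """Full normalization chain on a tidy raw density table.

    Quantile normalization runs per (condition, day) across the replicate
    columns; cyclic LOESS then pairs the control and drug columns of the
    same replicate within each day.
    """
    logged = log_transform(table, pseudocount=pseudocount) if table.stage == "raw" else table
    df = logged.data
    stage = "logged"

    wide = df.pivot_table(
        index="strain_id",
        columns=["condition", "replicate", "day"],
        values="value",
        aggfunc="first",
    )

    if quantile:
        for cond in df["condition"].unique():
            for day in df["day"].unique():
                cols = [c for c in wide.columns if c[0] == cond and c[2] == day]
                if len(cols) >= 2:
                    wide[cols] = quantile_normalize(wide[cols])
        stage = "quantile"

    if loess:
        conds = sorted(df["condition"].unique())
        if len(conds) == 2:
            ctrl, drug = conds[0], conds[1]
            if "control" in conds:
                ctrl = "control"
                drug = next(c for c in conds if c != "control")
            for day in df["day"].unique():
                pairs = []
                for rep in sorted(df["replicate"].unique()):
                    a, b = (drug, rep, day), (ctrl, rep, day)
                    if a in wide.columns and b in wide.columns:
                        pairs.append((a, b))
                if pairs:
                    cols = sorted({c for p in pairs for c in p})
                    wide[cols] = cyclic_loess(wide[cols], pairs, params)
            stage = "loess"

    long = wide.stack(["condition", "replicate", "day"], future_stack=True)
    long.name = "value"
    merged = df.drop(columns="value").merge(
        long.reset_index(), on=["strain_id", "condition", "replicate", "day"],
        how="left",
    )
    return DensityTable(merged, stage=stage)
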