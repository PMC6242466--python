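"""Tabular containers shared across the pipeline.

The central object is :class:`DensityTable`, a tidy table of per-colony
integrated densities indexed by strain x condition x replicate x day, with
the physical plate each value came from and a stage marker recording how far
through the transform/normalization chain the values are.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Allowed processing stages, in pipeline order.
STAGES = ("raw", "logged", "quantile", "loess")

#: Required columns of the tidy density table.
DENSITY_COLUMNS = (
    "strain_id",
    "condition",
    "replicate",
    "day",
    "plate_id",
    "value",
)


@dataclass
class DensityTable:
    """Per-colony densities in tidy (long) form.

    Parameters
    ----------
    data
        DataFrame with columns ``strain_id, condition, replicate, day,
        plate_id, value``. ``value`` holds raw integrated densities at stage
        ``raw`` and log2 densities afterwards.
    stage
        One of :data:`STAGES`.
    """

    data: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        missing = [c for c in DENSITY_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"density table is missing columns {missing}")

    def copy(self) -> "DensityTable":
        return DensityTable(self.data.copy(), self.stage)

    @property
    def strains(self) -> pd.Index:
        return pd.Index(sorted(self.data["strain_id"].unique()))

    @property
    def days(self) -> list:
        return sorted(self.data["day"].unique())

    @property
    def conditions(self) -> list:
        return sorted(self.data["condition"].unique())

    def pivot(self, condition, day) -> pd.DataFrame:
        """Strain x replicate value matrix for one (condition, day) slice."""
        sub = self.data[
            (self.data["condition"] == condition) & (self.data["day"] == day)
        ]
        return sub.pivot_table(
            index="strain_id", columns="replicate", values="value", aggfunc="first"
        )

    def with_values(self, values: pd.Series, stage: str) -> "DensityTable":
        """Return a copy with ``value`` replaced (aligned on row index)."""
        df = self.data.copy()
        df["value"] = values.reindex(df.index)
        return DensityTable(df, stage)


@dataclass
class ScreenTruth:
    """Ground truth of a simulated screen.

    ``table`` has one row per strain: ``strain_id``, ``baseline_log2``
    (expected control log2 density at day scale zero), ``effect_log2``
    (signed true drug shift, 0 for nulls) and ``direction`` in ``{+,-,0}``.
    """

    table: pd.DataFrame
    effect_days: tuple = field(default_factory=tuple)

    @property
    def spiked(self) -> pd.Index:
        t = self.table
        return pd.Index(t.loc[t["effect_log2"] != 0.0, "strain_id"])

    @property
    def nulls(self) -> pd.Index:
        t = self.table
        return pd.Index(t.loc[t["effect_log2"] == 0.0, "strain_id"])
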