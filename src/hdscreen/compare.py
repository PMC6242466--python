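"""Compilation of external per-gene datasets and overlap statistics.

External studies of the same perturbation come in five flavors, each with
its own compilation rule:

- ``deletion_fitness``: per-source calls of +1 (increased resistance), -1
  (increased sensitivity) or 0 (no effect), summed across sources.
- ``mrna``: per-gene mean change in expression across sources (a gene
  absent from a source contributes nothing to that source's mean).
- ``protein_abundance``: each source divided by its own standard deviation,
  then summed per gene.
- ``flux``: per compartment/timepoint top lists of relocalization Z-scores;
  a gene's score is the sum of its absolute Z-scores over the lists it
  appears in, 0 if in none.
- ``phospho``: qualitative sources contribute -1/+1 directly; quantitative
  sources are SD-normalized and added.

Overlap between two ranked datasets is scored by a one-sided
hypergeometric test of the intersection of their top fractions (1, 5, 10,
15, 20 and 25% by default) within the universe of genes present in both,
keeping the smallest p over the grid (reported uncorrected, with a
Bonferroni-corrected companion value for honesty).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CATEGORIES = ("deletion_fitness", "mrna", "protein_abundance", "flux", "phospho")

DEFAULT_FRACTIONS = (0.01, 0.05, 0.10, 0.15, 0.20, 0.25)


@dataclass
class RankedDataset:
    """A compiled external dataset: one score per gene plus its ranking."""

    scores: pd.Series
    category: str
    sources: tuple = ()

    def __post_init__(self) -> None:
        if self.scores.index.duplicated().any():
            raise ValueError("one score per gene required")

    @property
    def genes(self) -> pd.Index:
        return self.scores.index

    def ranking(self, signed: bool = False, ascending: bool = False) -> pd.Index:
        """Genes ordered by |score| descending (default) or signed score.

        Ties break by gene ID so the ranking is deterministic.
        """
        key = self.scores if signed else self.scores.abs()
        df = pd.DataFrame({"key": key, "gene": key.index})
        df = df.sort_values(["key", "gene"], ascending=[ascending, True])
        return pd.Index(df["gene"])

    def top_fraction(self, fraction: float, signed: bool = False) -> set:
        n = max(1, int(np.floor(fraction * len(self.scores))))
        return set(self.ranking(signed=signed)[:n])


@dataclass
class OverlapResult:
    fractions: tuple
    overlap_counts: tuple
    p_values: tuple
    universe_size: int
    min_p: float = field(init=False)
    min_p_corrected: float = field(init=False)

    def __post_init__(self) -> None:
        self.min_p = float(min(self.p_values))
        self.min_p_corrected = float(min(1.0, self.min_p * len(self.p_values)))

    @property
    def neg_log10_min_p(self) -> float:
        return float(-np.log10(self.min_p))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fraction": self.fractions,
                "overlap": self.overlap_counts,
                "p": self.p_values,
            }
        )


def _sd_normalized(records: pd.DataFrame) -> pd.Series:
    """Per-source SD normalization, then per-gene sum across sources."""
    parts = []
    for _, g in records.groupby("source_id"):
        sd = g["value"].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError("source with zero/undefined standard deviation")
        parts.append(g.set_index("gene_id")["value"] / sd)
    return pd.concat(parts).groupby(level=0).sum()


def compile_dataset(
    records: pd.DataFrame,
    category: str,
    flux_top: int = 100,
    flux_universe=None,
) -> RankedDataset:
    """Compile per-gene source records into one score per gene.

    ``records`` needs columns ``gene_id, value, source_id`` (``flux``
    additionally ``compartment`` and ``timepoint``; ``phospho`` a boolean
    ``qualitative`` per source). ``flux_universe`` optionally lists genes
    that were assayed but never reached a top list (they score 0).
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    rec = records.copy()
    if "source_id" not in rec.columns:
        rec["source_id"] = "s1"
    sources = tuple(sorted(map(str, rec["source_id"].unique())))

    if category == "deletion_fitness":
        if not rec["value"].isin([-1, 0, 1]).all():
            raise ValueError("deletion fitness values must be in {-1, 0, 1}")
        scores = rec.groupby("gene_id")["value"].sum()
    elif category == "mrna":
        per_source = rec.pivot_table(
            index="gene_id", columns="source_id", values="value", aggfunc="mean"
        )
        scores = per_source.mean(axis=1)  # absent genes skip that source
    elif category == "protein_abundance":
        scores = _sd_normalized(rec)
    elif category == "flux":
        if rec["value"].isna().any():
            raise ValueError("flux records with missing Z-scores")
        for colname in ("compartment", "timepoint"):
            if colname not in rec.columns:
                rec[colname] = "all"
        parts = []
        for _, g in rec.groupby(["source_id", "compartment", "timepoint"]):
            top = g.reindex(g["value"].abs().sort_values(ascending=False).index)
            parts.append(top.head(flux_top).set_index("gene_id")["value"].abs())
        scores = pd.concat(parts).groupby(level=0).sum()
        if flux_universe is not None:
            scores = scores.reindex(pd.Index(sorted(set(flux_universe))), fill_value=0.0)
    else:  # phospho
        if "qualitative" not in rec.columns:
            rec["qualitative"] = rec.groupby("source_id")["value"].transform(
                lambda v: v.isin([-1, 0, 1]).all()
            )
        qual = rec[rec["qualitative"].astype(bool)]
        quant = rec[~rec["qualitative"].astype(bool)]
        parts = []
        if len(qual):
            if not qual["value"].isin([-1, 0, 1]).all():
                raise ValueError("qualitative phospho values must be in {-1, 0, 1}")
            parts.append(qual.groupby("gene_id")["value"].sum())
        if len(quant):
            parts.append(_sd_normalized(quant))
        scores = pd.concat(parts).groupby(level=0).sum()

    scores = scores.sort_index()
    scores.index.name = "gene_id"
    return RankedDataset(scores=scores, category=category, sources=sources)


def hypergeom_p(overlap: int, n_a: int, n_b: int, universe: int) -> float:
    """One-sided P(X >= overlap) for |A| = n_a, |B| = n_b in the universe."""
    if overlap <= 0:
        return 1.0
    return float(stats.hypergeom.sf(overlap - 1, universe, n_a, n_b))


def overlap_significance(
    ds_a: RankedDataset,
    ds_b: RankedDataset,
    fractions: tuple = DEFAULT_FRACTIONS,
    signed: bool = False,
) -> OverlapResult:
    """Hypergeometric overlap scan over top fractions of two rankings.

    Both datasets are restricted to their shared universe before ranking.
    Top-set sizes round down (minimum one gene). The smallest p over the
    grid is reported without multiplicity correction (a corrected value is
    attached alongside).
    """
    universe = ds_a.genes.intersection(ds_b.genes)
    n = len(universe)
    if n == 0:
        raise ValueError("empty shared universe")
    if n < 20:
        raise ValueError(f"shared universe of {n} genes is too small (need >= 20)")
    a = RankedDataset(ds_a.scores.loc[universe], ds_a.category)
    b = RankedDataset(ds_b.scores.loc[universe], ds_b.category)

    counts, ps = [], []
    for f in fractions:
        top_a = a.top_fraction(f, signed=signed)
        top_b = b.top_fraction(f, signed=signed)
        k = len(top_a & top_b)
        counts.append(k)
        ps.append(hypergeom_p(k, len(top_a), len(top_b), n))
    return OverlapResult(
        fractions=tuple(fractions),
        overlap_counts=tuple(counts),
        p_values=tuple(ps),
        universe_size=n,
    )


def pairwise_overlap_matrix(datasets: dict, **kw) -> pd.DataFrame:
    """Symmetric matrix of -log10(min p) over all dataset pairs."""
    names = sorted(datasets)
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = overlap_significance(datasets[a], datasets[b], **kw)
            mat.loc[a, b] = mat.loc[b, a] = res.neg_log10_min_p
    return mat


def rank_screen_results(day_results: pd.DataFrame, mode: str = "pvalue") -> pd.Index:
    """Rank screen strains for comparison against external datasets.

    ``pvalue`` mode ranks by the best per-strain p-value ascending (ties by
    |delta| descending, then strain ID). ``signed`` mode ranks from the
    most significant decreased strain through non-significant strains to
    the most significant increased strain.
    """
    best = (
        day_results.assign(absdelta=day_results["delta"].abs())
        .sort_values(["p_raw", "absdelta"], ascending=[True, False])
        .groupby("strain_id", as_index=False)
        .first()
    )
    if mode == "pvalue":
        best = best.sort_values(
            ["p_raw", "absdelta", "strain_id"], ascending=[True, False, True]
        )
        return pd.Index(best["strain_id"])
    if mode != "signed":
        raise ValueError("mode must be 'pvalue' or 'signed'")
    # signed: decreased significant first, increased significant last
    key = np.where(
        best["delta"] < 0, np.log10(best["p_raw"].clip(lower=1e-300)),
        -np.log10(best["p_raw"].clip(lower=1e-300)),
    )
    best = best.assign(signed_key=key).sort_values(
        ["signed_key", "strain_id"], ascending=[True, True]
    )
    return pd.Index(best["strain_id"])


def screen_ranked_dataset(day_results: pd.DataFrame) -> RankedDataset:
    """The screen itself as a RankedDataset.

    Per strain, the best (smallest) raw p over days becomes the score
    ``sign(delta) * -log10(p)``, so ranking by |score| descending matches
    ranking by p-value ascending.
    """
    best = (
        day_results.assign(absdelta=day_results["delta"].abs())
        .sort_values(["p_raw", "absdelta"], ascending=[True, False])
        .groupby("strain_id", as_index=False)
        .first()
    )
    score = np.sign(best["delta"]) * -np.log10(best["p_raw"].clip(lower=1e-300))
    return RankedDataset(
        scores=pd.Series(score.to_numpy(), index=pd.Index(best["strain_id"])),
        category="screen",
    )


def running_overlap_curve(
    ranking: pd.Index,
    external_top: set,
    smoothing_span: float = 0.5,
) -> pd.DataFrame:
    """Running average membership of an external top set along a ranking.

    The binary membership indicator along the ranking is smoothed by a
    degree-0 local regression with uniform weights — a running mean over a
    window of ``smoothing_span`` times the ranking length, truncated at the
    ends. A membership fraction is an unbiased local estimate at every rank
    and, on a random top set, stays within the binomial band around the
    base rate. Returns rank positions, raw indicators and smoothed
    fractions in [0, 1].
    """
    if not external_top:
        raise ValueError("empty external top set")
    unknown = set(external_top) - set(ranking)
    if unknown:
        raise ValueError(f"{len(unknown)} external genes not in the ranking universe")
    if not 0.0 < smoothing_span <= 1.0:
        raise ValueError("smoothing_span must lie in (0, 1]")
    indicator = np.array([1.0 if g in external_top else 0.0 for g in ranking])
    n = indicator.size
    half = max(1, int(smoothing_span * n)) // 2
    csum = np.concatenate([[0.0], np.cumsum(indicator)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    smooth = (csum[hi] - csum[lo]) / (hi - lo)
    return pd.DataFrame(
        {
            "rank": np.arange(n),
            "gene": list(ranking),
            "member": indicator.astype(int),
            "smoothed": smooth,
        }
    )
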