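"""Synthetic screens with known ground truth.

Emulates a pinned colony-array chemical screen: thousands of strains arrayed
in 384/1,536 format, four replicate plates per condition, photographed over
two weeks. The generative model works on the log2 integrated-density scale:

    log2(density) = baseline + growth(day) + plate effect
                    [+ basal drug penalty(baseline) + true effect, on drug]
                    + replicate noise

The basal drug penalty is a smooth monotone function of baseline colony
size (small colonies are hit harder by the drug), which is exactly the
structure the cyclic LOESS stage downstream is meant to remove. Matched
synthetic "external" datasets correlated with the spiked truth, and toy
ontologies with annotations, make the comparison and enrichment stages
testable without any download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import DensityTable, ScreenTruth

DEFAULT_DAYS = (1, 2, 3, 4, 5, 7, 10, 12, 14)

EXTERNAL_CATEGORIES = (
    "deletion_fitness",
    "mrna",
    "protein_abundance",
    "flux",
    "phospho",
)


@dataclass
class BasalDrugCurve:
    """Monotone basal drug penalty as a function of baseline log2 density.

    Logistic in the baseline: small colonies receive close to the full
    ``amplitude`` (in log2 units, as a growth *penalty*), large colonies
    close to none. ``amplitude = 0`` gives a flat (no-op) curve.
    """

    amplitude: float = 0.5
    midpoint: float = 10.0
    width: float = 0.7

    def __call__(self, baseline_log2):
        b = np.asarray(baseline_log2, dtype=float)
        return -self.amplitude / (1.0 + np.exp((b - self.midpoint) / self.width))


@dataclass
class ScreenSimParams:
    """Study conditions of a simulated screen."""

    n_strains: int = 3504
    n_replicates: int = 4
    days: tuple = DEFAULT_DAYS
    plate_format: int = 1536
    spike_fraction: float = 0.05
    effect_size_log2: float = 0.5
    noise_sd_log2: float = 0.15
    plate_effect_sd: float = 0.05
    basal_drug_curve: BasalDrugCurve = field(default_factory=BasalDrugCurve)
    baseline_mean_log2: float = 10.0
    baseline_sd_log2: float = 1.0
    growth_max_log2: float = 3.0
    growth_tau_days: float = 2.0
    effect_days: tuple = ()  # empty = effect present on every day
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plate_format not in (384, 1536):
            raise ValueError("plate_format must be 384 or 1536")
        if not self.days or any(int(d) != d or d < 0 for d in self.days):
            raise ValueError("days must be a non-empty list of non-negative integers")
        if len(set(self.days)) != len(self.days):
            raise ValueError("days must be unique")
        if not 0.0 <= self.spike_fraction <= 1.0:
            raise ValueError("spike_fraction must lie in [0, 1]")
        if self.noise_sd_log2 < 0 or self.plate_effect_sd < 0 or self.baseline_sd_log2 < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_strains < 1 or self.n_replicates < 2:
            raise ValueError("need >= 1 strain and >= 2 replicates")
        extra = set(self.effect_days) - set(self.days)
        if extra:
            raise ValueError(f"effect_days {sorted(extra)} not in days")

    @property
    def n_plates(self) -> int:
        return math.ceil(self.n_strains / self.plate_format)

    def growth(self, day):
        d = np.asarray(day, dtype=float)
        return self.growth_max_log2 * d / (d + self.growth_tau_days)


def _strain_ids(n: int) -> np.ndarray:
    width = max(4, len(str(n)))
    return np.array([f"S{i:0{width}d}" for i in range(1, n + 1)])


def simulate_screen(params: ScreenSimParams) -> tuple[ScreenTruth, DensityTable]:
    """Simulate a full control-vs-drug screen.

    Returns the ground truth (per-strain baseline and signed true effect)
    and a raw-stage :class:`DensityTable` with one row per
    strain x condition x replicate x day. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_strains
    strains = _strain_ids(n)

    baseline = rng.normal(params.baseline_mean_log2, params.baseline_sd_log2, n)
    n_spike = round(params.spike_fraction * n)
    effects = np.zeros(n)
    spike_idx = rng.choice(n, size=n_spike, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_spike)
    effects[spike_idx] = signs * params.effect_size_log2

    direction = np.where(effects > 0, "+", np.where(effects < 0, "-", "0"))
    truth = ScreenTruth(
        pd.DataFrame(
            {
                "strain_id": strains,
                "baseline_log2": baseline,
                "effect_log2": effects,
                "direction": direction,
            }
        ),
        effect_days=tuple(params.effect_days),
    )

    conditions = ("control", "drug")
    days = np.asarray(params.days)
    effect_on = (
        np.isin(days, np.asarray(params.effect_days))
        if params.effect_days
        else np.ones(len(days), dtype=bool)
    )
    plate_of_strain = np.arange(n) // params.plate_format
    basal = params.basal_drug_curve(baseline)
    growth = params.growth(days)

    # one technical shift per physical plate (condition x replicate x plate),
    # constant across imaging days of that plate
    plate_shift = rng.normal(
        0.0, params.plate_effect_sd, (2, params.n_replicates, params.n_plates)
    )

    frames = []
    for ci, cond in enumerate(conditions):
        for rep in range(1, params.n_replicates + 1):
            shift = plate_shift[ci, rep - 1, plate_of_strain]
            # strains x days
            log2v = baseline[:, None] + growth[None, :] + shift[:, None]
            if cond == "drug":
                log2v = log2v + basal[:, None] + np.outer(effects, effect_on)
            log2v = log2v + rng.normal(
                0.0, params.noise_sd_log2, (n, len(days))
            )
            frames.append(
                pd.DataFrame(
                    {
                        "strain_id": np.repeat(strains, len(days)),
                        "condition": cond,
                        "replicate": rep,
                        "day": np.tile(days, n),
                        "plate_id": np.repeat(
                            np.array(
                                [f"{cond}_r{rep}_p{p + 1}" for p in plate_of_strain]
                            ),
                            len(days),
                        ),
                        "value": np.exp2(log2v).ravel(),
                    }
                )
            )
    table = DensityTable(pd.concat(frames, ignore_index=True), stage="raw")
    return truth, table


# ---------------------------------------------------------------------------
# plate rendering


def render_plate(
    densities: np.ndarray,
    grid,
    image_noise_sd: float = 0.0,
    seed: int = 0,
    background: float = 100.0,
    ref_density: float = 1024.0,
    ref_sigma: float = 2.5,
    min_sigma: float = 1.8,
) -> np.ndarray:
    """Render one plate image from per-position densities (NaN = empty).

    Colonies are radially smooth super-Gaussian discs whose Gaussian scale
    grows with the square root of density (so the peak intensity stays
    constant until the radius cap bites); each colony's pixel sum above
    background equals its density exactly, up to the window clipping at the
    image edge. ``min_sigma`` floors the footprint of the faintest colonies
    (pinned arrays deposit a pin-sized spot even when growth is minimal).
    """
    from .quant import grid_centers

    densities = np.asarray(densities, dtype=float).reshape(-1)
    centers = grid_centers(grid).reshape(-1, 2)
    if densities.size != centers.shape[0]:
        raise ValueError(
            f"{densities.size} densities for {centers.shape[0]} grid positions"
        )
    pitch = min(grid.pitch_x, grid.pitch_y)
    margin = int(math.ceil(pitch))
    width = int(math.ceil(centers[:, 0].max())) + margin + 1
    height = int(math.ceil(centers[:, 1].max())) + margin + 1
    img = np.zeros((height, width), dtype=float)

    sigma_cap = 0.30 * pitch  # keep tails clear of the neighboring position
    peak = ref_density / (math.pi * math.gamma(1.5) * ref_sigma**2)
    for (cx, cy), dens in zip(centers, densities):
        if not np.isfinite(dens) or dens <= 0:
            continue
        sigma = min(max(ref_sigma * math.sqrt(dens / ref_density), min_sigma),
                    sigma_cap)
        half = int(math.ceil(3.0 * sigma)) + 1
        x0, x1 = max(0, int(cx) - half), min(width, int(cx) + half + 1)
        y0, y1 = max(0, int(cy) - half), min(height, int(cy) + half + 1)
        xs = np.arange(x0, x1) - cx
        ys = np.arange(y0, y1) - cy
        r2 = (ys[:, None] ** 2 + xs[None, :] ** 2) / sigma**2
        profile = peak * np.exp(-(r2**2))  # super-Gaussian, flat top
        s = profile.sum()
        if s > 0:
            profile *= dens / s  # pixel sum above background == density
        img[y0:y1, x0:x1] += profile

    img += background
    if image_noise_sd > 0:
        rng = np.random.default_rng(seed)
        img += rng.normal(0.0, image_noise_sd, img.shape)
    return np.clip(img, 0.0, 65535.0)


def render_plates(
    table: DensityTable,
    grid,
    image_noise_sd: float = 0.0,
    seed: int = 0,
    **render_kw,
) -> tuple[dict, pd.DataFrame]:
    """Render every physical plate x day of a raw density table.

    Strains are assigned to grid positions in sorted-ID order within each
    plate. Returns ``(images, layout)`` where ``images`` maps
    ``(plate_id, day)`` to a 2-D array and ``layout`` has one row per
    occupied grid position (``plate_id, row, col, strain_id`` plus the true
    center coordinates for oracle use).
    """
    from .quant import grid_centers

    if table.stage != "raw":
        raise ValueError("render_plates expects a raw-stage table")
    n_positions = grid.n_rows * grid.n_cols
    centers = grid_centers(grid)

    layout_rows = []
    images = {}
    df = table.data
    for plate_id, plate_df in df.groupby("plate_id"):
        strains = np.sort(plate_df["strain_id"].unique())
        if strains.size > n_positions:
            raise ValueError(
                f"plate {plate_id}: {strains.size} strains exceed "
                f"{n_positions} grid positions"
            )
        pos_of = {s: i for i, s in enumerate(strains)}
        for i, s in enumerate(strains):
            r, c = divmod(i, grid.n_cols)
            layout_rows.append(
                {
                    "plate_id": plate_id,
                    "row": r,
                    "col": c,
                    "strain_id": s,
                    "center_x": centers[r, c, 0],
                    "center_y": centers[r, c, 1],
                }
            )
        for day, day_df in plate_df.groupby("day"):
            dens = np.full(n_positions, np.nan)
            for s, v in zip(day_df["strain_id"], day_df["value"]):
                dens[pos_of[s]] = v
            images[(plate_id, day)] = render_plate(
                dens,
                grid,
                image_noise_sd=image_noise_sd,
                seed=(seed + abs(hash((plate_id, day))) % 100000),
                **render_kw,
            )
    return images, pd.DataFrame(layout_rows)


# ---------------------------------------------------------------------------
# matched external datasets


def simulate_external_datasets(
    truth: ScreenTruth,
    category: str,
    corr: float,
    seed: int = 0,
    n_sources: int = 4,
    n_flux_lists: int = 8,
    flux_top: int = 100,
):
    """Emit one compiled external dataset correlated with the spiked truth.

    Continuous categories (mrna, protein_abundance, phospho) draw
    ``score = corr * z + sqrt(1 - corr^2) * noise`` with ``z`` the
    standardized true effect, so ``corr = 1`` is noiseless and ``corr = 0``
    is independent of the truth. ``deletion_fitness`` sums per-source
    {-1, 0, +1} calls whose sign agrees with the truth with probability
    ``(1 + corr) / 2``; ``flux`` builds per-list top-``flux_top`` Z-score
    lists and sums absolute Z-scores.
    """
    from .compare import RankedDataset

    if category not in EXTERNAL_CATEGORIES:
        raise ValueError(
            f"unknown category {category!r}; expected one of {EXTERNAL_CATEGORIES}"
        )
    if not 0.0 <= corr <= 1.0:
        raise ValueError("corr must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = truth.table["strain_id"].to_numpy()
    eff = truth.table["effect_log2"].to_numpy(dtype=float)
    sd = eff.std()
    z = eff / sd if sd > 0 else np.zeros_like(eff)
    n = genes.size

    if category == "deletion_fitness":
        total = np.zeros(n)
        p_agree = (1.0 + corr) / 2.0
        for _ in range(n_sources):
            call = np.zeros(n)
            nonzero = np.where(
                eff != 0, rng.random(n) < 0.8, rng.random(n) < 0.1
            )
            agree = rng.random(n) < p_agree
            base_sign = np.where(eff != 0, np.sign(eff), rng.choice([-1, 1], n))
            call[nonzero] = np.where(agree, base_sign, -base_sign)[nonzero]
            total += call
        scores = pd.Series(total, index=genes)
    elif category == "flux":
        total = np.zeros(n)
        noise_w = math.sqrt(max(0.0, 1.0 - corr**2))
        for _ in range(n_flux_lists):
            latent = corr * np.abs(z) + noise_w * rng.normal(size=n)
            top = np.argsort(-latent)[: min(flux_top, n)]
            total[top] += np.abs(latent[top])
        scores = pd.Series(total, index=genes)
    else:
        noise_w = math.sqrt(max(0.0, 1.0 - corr**2))
        scores = pd.Series(corr * z + noise_w * rng.normal(size=n), index=genes)
    return RankedDataset(scores=scores, category=category)


# ---------------------------------------------------------------------------
# toy ontologies


def simulate_ontology(n_terms: int, n_genes: int | None = None, seed: int = 0,
                      genes=None):
    """Random rooted ontology DAG with gene annotations.

    Term 0 is the root; every later term attaches below one or two earlier
    terms. Genes (generated IDs, or the explicit ``genes`` list) are
    annotated directly on leaf terms (one or two leaves each) and
    propagated to ancestors, so every child's annotation is a subset of
    each parent's by construction.
    """
    from .enrich import OntologyDAG

    if n_terms < 1:
        raise ValueError("need n_terms >= 1")
    if genes is None:
        if n_genes is None:
            raise ValueError("give n_genes or an explicit gene list")
        gwidth = max(4, len(str(n_genes)))
        genes = [f"g{i:0{gwidth}d}" for i in range(1, n_genes + 1)]
    else:
        genes = list(genes)
    rng = np.random.default_rng(seed)
    width = max(2, len(str(n_terms)))
    terms = [f"T{i:0{width}d}" for i in range(n_terms)]

    edges = []  # (child, parent)
    for i in range(1, n_terms):
        k = 1 if i < 3 or rng.random() < 0.7 else 2
        parents = rng.choice(i, size=min(k, i), replace=False)
        for p in parents:
            edges.append((terms[i], terms[int(p)]))

    children = {t: [] for t in terms}
    for child, parent in edges:
        children[parent].append(child)
    leaves = [t for t in terms if not children[t]]

    annotations = {t: set() for t in terms}
    for g in genes:
        k = 1 if rng.random() < 0.7 else 2
        for leaf in rng.choice(len(leaves), size=min(k, len(leaves)), replace=False):
            annotations[leaves[int(leaf)]].add(g)

    dag = OntologyDAG.from_edges(edges, annotations, terms=terms)
    dag.propagate()
    return dag
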