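"""End-to-end orchestration of the screen analysis.

``run_screen`` drives quantify (or simulate/load) -> log2 -> quantile ->
cyclic LOESS -> per-day regularized test -> BH -> multi-day hit calling,
with optional external-dataset comparison and conditional enrichment, and
records a manifest (versions, parameters, seed, per-stage row counts) that
suffices to re-run the pipeline bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .compare import (
    DEFAULT_FRACTIONS,
    overlap_significance,
    running_overlap_curve,
    screen_ranked_dataset,
)
from .difftest import TestParams, call_hits, hit_sets, test_all_days
from .enrich import conditional_enrichment, enrichment_map
from .io import read_density_table, read_image, read_tsv, write_density_table, write_tsv
from .normalize import LoessParams, normalize_table
from .simulate import (
    EXTERNAL_CATEGORIES,
    ScreenSimParams,
    simulate_external_datasets,
    simulate_ontology,
    simulate_screen,
)
from .tables import DensityTable


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass
class ScreenConfig:
    """Declarative configuration of a full run.

    Exactly one input mode applies: a pre-quantified density table
    (``density_in``), plate images with a layout (``image_table`` +
    ``layout_in``), or simulation (the default).
    """

    seed: int = 0
    out_dir: str | None = None
    density_in: str | None = None
    image_table: str | None = None  # TSV: image_path, condition, replicate, day, plate_id
    layout_in: str | None = None
    sim: dict = field(default_factory=dict)
    pseudocount: float = 1.0
    loess: dict = field(default_factory=dict)
    test: dict = field(default_factory=dict)
    fractions: tuple = DEFAULT_FRACTIONS
    compare_corr: float = 0.6
    compare_categories: tuple = EXTERNAL_CATEGORIES
    enrich_n_terms: int = 30
    enrich_alpha: float = 0.05
    do_normalize: bool = True
    do_test: bool = True
    do_hits: bool = True
    do_compare: bool = False
    do_enrich: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        cfg = cls(**d)
        for key in ("density_in", "image_table", "layout_in"):
            path = getattr(cfg, key)
            if path is not None and not os.path.exists(path):
                raise ValueError(f"{key} path {path!r} does not exist")
        return cfg

    @classmethod
    def from_json(cls, path) -> "ScreenConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _quantify_images(config: ScreenConfig) -> DensityTable:
    from .quant import estimate_grid, quantify_plate

    meta = read_tsv(config.image_table)
    layout = read_tsv(config.layout_in) if config.layout_in else None
    rows = []
    for _, rec in meta.iterrows():
        img = read_image(rec["image_path"])
        fmt = int(rec.get("plate_format", 1536))
        grid = estimate_grid(img, format_hint=fmt)
        sub_layout = None
        if layout is not None:
            sub_layout = layout[layout["plate_id"] == rec["plate_id"]]
        q = quantify_plate(img, grid, layout=sub_layout)
        q = q.dropna(subset=["strain_id"])
        rows.append(
            pd.DataFrame(
                {
                    "strain_id": q["strain_id"],
                    "condition": rec["condition"],
                    "replicate": rec["replicate"],
                    "day": rec["day"],
                    "plate_id": rec["plate_id"],
                    "value": q["integrated_density"],
                }
            )
        )
    return DensityTable(pd.concat(rows, ignore_index=True), stage="raw")


def run_screen(config: ScreenConfig) -> dict:
    """Run the configured stages; returns the results bundle + manifest."""
    bundle: dict = {}
    manifest: dict = {
        "hdscreen_version": __version__,
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stages": {},
    }

    # --- input / quantification -------------------------------------------
    truth = None
    try:
        if config.density_in:
            table = read_density_table(config.density_in)
        elif config.image_table:
            table = _quantify_images(config)
        else:
            params = ScreenSimParams(**{"seed": config.seed, **config.sim})
            truth, table = simulate_screen(params)
            bundle["truth"] = truth
            manifest["stages"]["simulate"] = {"n_strains": params.n_strains}
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001 - rewrap with the stage name
        raise StageError("input", str(e)) from e
    bundle["density"] = table
    manifest["stages"]["density"] = {"rows": len(table.data)}

    # --- normalization ----------------------------------------------------
    if config.do_normalize:
        try:
            normalized = normalize_table(
                table,
                pseudocount=config.pseudocount,
                params=LoessParams(**config.loess),
            )
        except Exception as e:  # noqa: BLE001
            raise StageError("normalize", str(e)) from e
        bundle["normalized"] = normalized
        manifest["stages"]["normalize"] = {
            "rows": len(normalized.data),
            "stage": normalized.stage,
        }
    else:
        normalized = None

    # --- per-day testing and hit calling ----------------------------------
    test_params = TestParams(**config.test)
    if config.do_test:
        if normalized is None:
            raise StageError("test", "testing requires the normalize stage")
        try:
            day_results = test_all_days(normalized, test_params)
        except Exception as e:  # noqa: BLE001
            raise StageError("test", str(e)) from e
        bundle["day_results"] = day_results
        manifest["stages"]["test"] = {"rows": len(day_results)}

        if config.do_hits:
            hits = call_hits(day_results, test_params)
            bundle["hits"] = hits
            up, down = hit_sets(hits)
            manifest["stages"]["hits"] = {
                "n_hits": int(hits["is_hit"].sum()),
                "n_up": len(up),
                "n_down": len(down),
            }

    # --- external-dataset comparison --------------------------------------
    if config.do_compare:
        if truth is None or "day_results" not in bundle:
            raise StageError(
                "compare", "comparison needs simulated truth and test results"
            )
        screen_ds = screen_ranked_dataset(bundle["day_results"])
        overlaps = {}
        curves = {}
        for i, cat in enumerate(config.compare_categories):
            ext = simulate_external_datasets(
                truth, cat, corr=config.compare_corr, seed=config.seed + 101 + i
            )
            res = overlap_significance(screen_ds, ext, fractions=config.fractions)
            overlaps[cat] = res
            from .compare import rank_screen_results

            ranking = rank_screen_results(bundle["day_results"], mode="pvalue")
            ext_top = ext.top_fraction(0.20) & set(ranking)
            if ext_top:
                curves[cat] = running_overlap_curve(ranking, ext_top)
        bundle["overlaps"] = overlaps
        bundle["curves"] = curves
        manifest["stages"]["compare"] = {
            cat: res.min_p for cat, res in overlaps.items()
        }

    # --- enrichment -------------------------------------------------------
    if config.do_enrich:
        if "hits" not in bundle:
            raise StageError("enrich", "enrichment needs called hits")
        universe = set(table.strains)
        dag = simulate_ontology(
            config.enrich_n_terms, genes=sorted(universe), seed=config.seed + 997
        )
        up, down = hit_sets(bundle["hits"])
        enr = {}
        maps = {}
        for name, hset in (("up", up), ("down", down)):
            terms = conditional_enrichment(hset, universe, dag, alpha=config.enrich_alpha)
            enr[name] = terms
            maps[name] = enrichment_map(terms)
        bundle["enrichment"] = enr
        bundle["enrichment_edges"] = maps
        manifest["stages"]["enrich"] = {
            name: len(terms) for name, terms in enr.items()
        }

    bundle["manifest"] = manifest
    if config.out_dir:
        _write_bundle(bundle, config.out_dir)
    return bundle


def _write_bundle(bundle: dict, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    if "truth" in bundle:
        write_tsv(bundle["truth"].table, os.path.join(out_dir, "truth.tsv"))
    write_density_table(bundle["density"], os.path.join(out_dir, "density.tsv"))
    if "normalized" in bundle:
        write_density_table(bundle["normalized"], os.path.join(out_dir, "normalized.tsv"))
    if "day_results" in bundle:
        write_tsv(bundle["day_results"], os.path.join(out_dir, "day_results.tsv"))
    if "hits" in bundle:
        write_tsv(bundle["hits"], os.path.join(out_dir, "hits.tsv"))
    if "overlaps" in bundle:
        frames = []
        for cat, res in bundle["overlaps"].items():
            f = res.as_frame()
            f.insert(0, "category", cat)
            frames.append(f)
        write_tsv(pd.concat(frames, ignore_index=True),
                  os.path.join(out_dir, "overlaps.tsv"))
    if "enrichment_edges" in bundle:
        for name, edges in bundle["enrichment_edges"].items():
            write_tsv(edges, os.path.join(out_dir, f"enrichment_map_{name}.tsv"))
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(bundle["manifest"], fh, indent=2, default=str)
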