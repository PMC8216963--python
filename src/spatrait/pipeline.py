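"""Orchestration: census filtering, full analysis runs, and reporting.

The study protocol analyses two life stages separately — saplings (DBH in
the closed interval [1, 3] cm) and adult trees (DBH strictly > 10 cm) — and
keeps only species with at least 50 stems in the stage, so that point
pattern estimates are stable.  For each stage x statistic x radius x trait
the pipeline chains: association analysis -> trait distances -> screening
and comparison mixed models -> mechanism label, and writes tidy CSV/JSON
outputs plus a manifest with content hashes for reproducibility checks.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .synthetic import Window, read_census, read_traits, read_window
from .point_patterns import (
    associations_to_frame,
    ordered_pairs,
    pairwise_association_analysis,
)
from .trait_distances import pairwise_trait_distances, standardize_distances
from .models import (
    compare_strengths,
    fit_mixed_model,
    interpret_mechanism,
    significance_tier,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StageFilter",
    "SAPLING",
    "ADULT",
    "RunConfig",
    "filter_census",
    "association_proportions",
    "abundance_coverage",
    "analyse_stage",
    "infer_mechanism",
    "run_full_analysis",
    "load_config",
]


@dataclass(frozen=True)
class StageFilter:
    """DBH interval plus minimum per-species abundance for one life stage."""

    name: str
    dbh_min: float
    dbh_max: float | None = None
    min_abundance: int = 50
    include_min: bool = True   # closed lower bound?
    include_max: bool = True   # closed upper bound?

    def __post_init__(self) -> None:
        if self.dbh_min <= 0:
            raise ValueError("dbh_min must be positive")
        if self.dbh_max is not None and self.dbh_max <= self.dbh_min:
            raise ValueError("dbh_max must exceed dbh_min")
        if self.min_abundance < 1:
            raise ValueError("min_abundance must be >= 1")

    def mask(self, dbh: pd.Series) -> pd.Series:
        lo = dbh >= self.dbh_min if self.include_min else dbh > self.dbh_min
        if self.dbh_max is None:
            return lo
        hi = dbh <= self.dbh_max if self.include_max else dbh < self.dbh_max
        return lo & hi


# Saplings occupy the closed DBH interval [1, 3] cm; adults are strictly
# above 10 cm (the interval wording is followed literally).
SAPLING = StageFilter("sapling", 1.0, 3.0, 50)
ADULT = StageFilter("adult", 10.0, None, 50, include_min=False)


def filter_census(census: pd.DataFrame, stage: StageFilter):
    """Stems inside the stage's DBH interval, species above min abundance.

    Returns ``(filtered census, species counts)``; species whose in-stage
    count falls below ``min_abundance`` are dropped entirely for the stage.
    """
    in_stage = census[stage.mask(census["dbh"])]
    counts = in_stage["species_id"].value_counts()
    keep = counts[counts >= stage.min_abundance]
    filtered = in_stage[in_stage["species_id"].isin(keep.index)].reset_index(drop=True)
    if filtered.empty:
        logger.warning("stage %s: no stems pass the filter", stage.name)
    return filtered, keep.sort_index()


def abundance_coverage(stage_counts, total_individuals: int) -> float:
    """Percentage of all individuals covered by the retained stages."""
    if total_individuals <= 0:
        raise ValueError("total_individuals must be positive")
    return 100.0 * float(np.sum(stage_counts)) / float(total_individuals)


def association_proportions(assoc: pd.DataFrame) -> pd.DataFrame:
    """Proportions of attraction/repulsion/independence per statistic x radius.

    Records flagged degenerate (zero null variance) are excluded, with a
    logged count; within each cell the three proportions sum to one.
    """
    if assoc.empty:
        raise ValueError("no association records")
    n_deg = int(assoc["degenerate_flag"].sum()) if "degenerate_flag" in assoc else 0
    if n_deg:
        logger.warning("excluding %d degenerate records from proportions", n_deg)
        assoc = assoc[~assoc["degenerate_flag"]]
    out = (
        assoc.groupby(["statistic", "r"])["class"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=["attraction", "repulsion", "independence"], fill_value=0.0)
        .reset_index()
    )
    return out


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    census_path: str
    traits_path: str
    window_path: str
    output_dir: str
    stages: list = field(default_factory=lambda: [SAPLING, ADULT])
    radii: tuple = (5.0, 30.0, 50.0)
    statistics: tuple = ("pcf", "D")
    traits: list | None = None       # None -> all available + integrated PCA
    n_sim: int = 999
    alpha: float = 0.05
    joint_comparison: bool = False   # separate single-predictor fits by default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sim < 2:
            raise ValueError("n_sim must be >= 2")
        if any(r <= 0 for r in self.radii):
            raise ValueError("radii must be positive")


def load_config(path) -> RunConfig:
    """Read a YAML/JSON mapping mirroring :class:`RunConfig`."""
    raw = yaml.safe_load(Path(path).read_text())
    stages = []
    for s in raw.pop("stages", []):
        stages.append(StageFilter(**s) if isinstance(s, dict) else {"sapling": SAPLING, "adult": ADULT}[s])
    cfg = RunConfig(**raw)
    if stages:
        cfg.stages = stages
    return cfg


def analyse_stage(
    census: pd.DataFrame,
    traits: pd.DataFrame,
    window: Window,
    stage: StageFilter,
    radii=(5.0, 30.0, 50.0),
    statistics=("pcf", "D"),
    trait_names=None,
    n_sim: int = 999,
    alpha: float = 0.05,
    joint_comparison: bool = False,
    seed=0,
):
    """Association records, standardized distances and model results for one stage.

    Returns a dict with the filtered census, the association frame, the
    distance set, a model-summary frame, a comparison frame and the
    mechanism labels per statistic x radius x trait.
    """
    filtered, counts = filter_census(census, stage)
    species = list(counts.index)
    if len(species) < 2:
        logger.warning("stage %s: fewer than 2 species; skipping", stage.name)
        return None
    records = pairwise_association_analysis(
        filtered, window, radii=radii, statistics=statistics,
        n_sim=n_sim, alpha=alpha, seed=seed,
    )
    assoc = associations_to_frame(records)
    distances = standardize_distances(
        pairwise_trait_distances(traits, traits=trait_names, species=species)
    )
    model_rows, comparison_rows, mechanisms = [], [], []
    usable = assoc[~assoc["degenerate_flag"]]
    for (stat, r), zcell in usable.groupby(["statistic", "r"]):
        for trait, dcell in distances.data.groupby("trait"):
            merged = zcell.merge(dcell, on=["focal_id", "other_id"], how="inner")
            try:
                screen = fit_mixed_model(
                    merged, ["absolute_std"],
                    metadata={"stage": stage.name, "statistic": stat, "r": r, "trait": trait},
                )
                if joint_comparison:
                    joint = fit_mixed_model(merged, ["absolute_std", "hierarchical_std"])
                    comp = compare_strengths(joint, predictor_abs="absolute_std",
                                             predictor_hier="hierarchical_std")
                else:
                    hier = fit_mixed_model(merged, ["hierarchical_std"])
                    comp = compare_strengths(screen, hier)
            except (ValueError, RuntimeError) as exc:
                logger.warning("model failed for %s/%s r=%g trait=%s: %s",
                               stage.name, stat, r, trait, exc)
                continue
            b = screen.slopes["absolute_std"]
            p = screen.slope_p["absolute_std"]
            label = interpret_mechanism(b, p, comp, alpha=alpha)
            model_rows.append({
                "stage": stage.name, "statistic": stat, "r": r, "trait": trait,
                "intercept": screen.intercept, "b_absolute": b, "se": screen.slope_se["absolute_std"],
                "p": p, "tier": significance_tier(p), "r2c": screen.r2c,
                "converged": screen.converged, "singular": screen.singular,
                "n_pairs": screen.n_obs, "n_focal": screen.n_groups,
            })
            comparison_rows.append({
                "stage": stage.name, "statistic": stat, "r": r, "trait": trait,
                "t": comp.t, "p": comp.p, "tier": comp.tier,
                "mean_abs_strength": comp.mean_absolute,
                "mean_hier_strength": comp.mean_hierarchical,
                "direction": comp.direction,
            })
            mechanisms.append({
                "stage": stage.name, "statistic": stat, "r": r, "trait": trait,
                "mechanism": label,
            })
    return {
        "stage": stage.name,
        "census": filtered,
        "species_counts": counts,
        "associations": assoc,
        "proportions": association_proportions(assoc),
        "distances": distances,
        "models": pd.DataFrame(model_rows),
        "comparisons": pd.DataFrame(comparison_rows),
        "mechanisms": pd.DataFrame(mechanisms),
    }


def infer_mechanism(
    census: pd.DataFrame,
    traits: pd.DataFrame,
    window: Window,
    statistic: str = "D",
    r: float = 5.0,
    trait: str = "PCA",
    n_sim: int = 99,
    alpha: float = 0.05,
    min_abundance: int = 10,
    seed=0,
) -> str:
    """End-to-end mechanism label for one community at one statistic/radius.

    Convenience wrapper used to validate scenario recovery: all stems enter
    (no stage split), the integrated PCA trait is the default predictor, and
    the label follows the screening + comparison decision tree.
    """
    stage = StageFilter("all", dbh_min=0.5, min_abundance=min_abundance)
    res = analyse_stage(
        census, traits, window, stage,
        radii=(r,), statistics=(statistic,), trait_names=None,
        n_sim=n_sim, alpha=alpha, seed=seed,
    )
    if res is None or res["mechanisms"].empty:
        return "none_detected"
    cell = res["mechanisms"].query("trait == @trait")
    if cell.empty:
        return "none_detected"
    return str(cell["mechanism"].iloc[0])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the whole chain for every configured stage and write outputs.

    Produces per-stage associations, proportions, distances, model summaries,
    comparisons and mechanism labels as CSV, an aggregated mechanism JSON,
    and a manifest (config, seed, package version, timings, content hash per
    output file).  Reruns with the same config reproduce identical hashes.
    """
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    census = read_census(config.census_path)
    traits = read_traits(config.traits_path)
    window = read_window(config.window_path)

    outputs, mechanisms, errors = {}, [], []
    for stage in config.stages:
        try:
            res = analyse_stage(
                census, traits, window, stage,
                radii=config.radii, statistics=config.statistics,
                trait_names=config.traits, n_sim=config.n_sim, alpha=config.alpha,
                joint_comparison=config.joint_comparison, seed=config.seed,
            )
        except Exception as exc:  # partial outputs are preserved
            logger.exception("stage %s failed", stage.name)
            errors.append({"stage": stage.name, "error": str(exc)})
            continue
        if res is None:
            errors.append({"stage": stage.name, "error": "fewer than 2 species"})
            continue
        for key, frame in (
            ("associations", res["associations"]),
            ("proportions", res["proportions"]),
            ("distances", res["distances"].data),
            ("models", res["models"]),
            ("comparisons", res["comparisons"]),
            ("mechanisms", res["mechanisms"]),
        ):
            path = outdir / f"{stage.name}_{key}.csv"
            frame.to_csv(path, index=False)
            outputs[f"{stage.name}_{key}"] = path
        mechanisms.extend(res["mechanisms"].to_dict("records"))

    mech_path = outdir / "mechanisms.json"
    mech_path.write_text(json.dumps(mechanisms, indent=2, default=float))
    outputs["mechanisms_json"] = mech_path

    manifest = {
        "config": {
            **{k: v for k, v in asdict(config).items() if k != "stages"},
            "stages": [asdict(s) for s in config.stages],
        },
        "version": __version__,
        "seed": config.seed,
        "elapsed_s": round(time.time() - t0, 3),
        "errors": errors,
        "outputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in outputs.items()},
    }
    # the manifest hash map excludes the timing field by construction
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
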