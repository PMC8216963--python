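"""Absolute and hierarchical trait distances plus the integrated PCA axis.

For an ordered species pair (i, j) with the focal species first, the
absolute trait distance |t_i - t_j| is a proxy for niche difference
(dissimilarity) and the hierarchical trait distance t_i - t_j a proxy for
competitive-rank (fitness) difference.  An integrated trait is built as the
species scores on the first axis of a PCA of the six-trait table
(correlation-matrix PCA, since the traits carry heterogeneous units).

Axis signs of a PCA are arbitrary; here axis 1 is oriented so that the SLA
loading is positive.  Hierarchical distances on the integrated trait flip
sign with the axis orientation, so any directional interpretation must be
made relative to this convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .point_patterns import ordered_pairs
from .synthetic import TRAIT_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "TraitDistanceSet",
    "absolute_distance",
    "hierarchical_distance",
    "max_height",
    "integrated_trait_scores",
    "pairwise_trait_distances",
    "standardize_distances",
]

INTEGRATED = "PCA"


def absolute_distance(t_i, t_j):
    """|t_i - t_j| (trait dissimilarity; symmetric, non-negative)."""
    t_i, t_j = np.asarray(t_i, dtype=float), np.asarray(t_j, dtype=float)
    if not (np.isfinite(t_i).all() and np.isfinite(t_j).all()):
        raise ValueError("trait values must be finite")
    return np.abs(t_i - t_j)


def hierarchical_distance(t_i, t_j):
    """t_i - t_j with the focal species first (trait hierarchy; antisymmetric)."""
    t_i, t_j = np.asarray(t_i, dtype=float), np.asarray(t_j, dtype=float)
    if not (np.isfinite(t_i).all() and np.isfinite(t_j).all()):
        raise ValueError("trait values must be finite")
    return t_i - t_j


def max_height(heights, q: float = 0.99) -> float:
    """Species maximum height as the 99% quantile of per-stem heights.

    Uses linear interpolation between order statistics (the conventional
    default quantile definition).
    """
    heights = np.asarray(heights, dtype=float)
    heights = heights[np.isfinite(heights)]
    if heights.size == 0:
        raise ValueError("no finite height measurements")
    return float(np.quantile(heights, q, method="linear"))


def integrated_trait_scores(trait_table: pd.DataFrame, traits=None):
    """Species scores on PCA axis 1 of the centred/scaled trait matrix.

    Returns ``(scores, variance_share, loadings)``: a Series of axis-1
    scores indexed by species, the axis-1 share of total variance, and the
    axis-1 loadings.  Axis sign is fixed so the SLA loading (or, failing
    that, the first trait's loading) is positive.
    """
    traits = list(traits) if traits is not None else [
        c for c in TRAIT_COLUMNS if c in trait_table.columns
    ]
    if len(traits) < 2:
        raise ValueError("PCA needs at least 2 traits")
    sub = trait_table.set_index("species_id")[traits].astype(float)
    if sub.isna().any().any():
        raise ValueError("PCA input must have no missing values")
    if len(sub) < 2:
        raise ValueError("PCA needs at least 2 species")
    x = sub.to_numpy()
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0.0):
        bad = [t for t, s in zip(traits, sd) if s == 0.0]
        raise ValueError(f"constant trait column(s): {bad}")
    xs = (x - mean) / sd
    _, svals, vt = np.linalg.svd(xs, full_matrices=False)
    axis1 = vt[0]
    anchor = traits.index("SLA") if "SLA" in traits else 0
    if axis1[anchor] < 0:
        axis1 = -axis1
    scores = pd.Series(xs @ axis1, index=sub.index, name="pca_score")
    share = float(svals[0] ** 2 / (svals**2).sum())
    loadings = pd.Series(axis1, index=traits, name="loading")
    return scores, share, loadings


def pairwise_trait_distances(
    trait_table: pd.DataFrame,
    traits=None,
    include_integrated: bool = True,
    species=None,
) -> pd.DataFrame:
    """Long table of raw absolute/hierarchical distances per ordered pair.

    One row per (focal, other, trait); the integrated PCA axis is appended
    as trait ``"PCA"``.  Pairs with a missing value for a trait are excluded
    from that trait only, with a logged count.
    """
    traits = list(traits) if traits is not None else [
        c for c in TRAIT_COLUMNS if c in trait_table.columns
    ]
    tab = trait_table.copy()
    if species is not None:
        tab = tab[tab["species_id"].isin(set(species))]
    tab = tab.set_index("species_id")
    values = {t: tab[t].astype(float) for t in traits}
    if include_integrated:
        complete = tab.dropna(subset=traits)
        scores, share, _ = integrated_trait_scores(
            complete.reset_index(), traits=traits
        )
        values[INTEGRATED] = scores
        logger.info("integrated PCA axis 1 explains %.1f%% of trait variance", 100 * share)
    pairs = ordered_pairs(tab.index)
    focal = np.array([p[0] for p in pairs])
    other = np.array([p[1] for p in pairs])
    frames = []
    for trait, vals in values.items():
        ti = vals.reindex(focal).to_numpy()
        tj = vals.reindex(other).to_numpy()
        ok = np.isfinite(ti) & np.isfinite(tj)
        dropped = int((~ok).sum())
        if dropped:
            logger.warning("trait %s: excluded %d pairs with missing values", trait, dropped)
        frames.append(
            pd.DataFrame(
                {
                    "focal_id": focal[ok],
                    "other_id": other[ok],
                    "trait": trait,
                    "absolute_raw": np.abs(ti[ok] - tj[ok]),
                    "hierarchical_raw": ti[ok] - tj[ok],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class TraitDistanceSet:
    """Standardized pairwise distances plus the scaling metadata."""

    data: pd.DataFrame
    scaling: pd.DataFrame


def standardize_distances(distances: pd.DataFrame) -> TraitDistanceSet:
    """Centre and scale each predictor to mean 0, sd 1 within each trait.

    Standardization uses the sample (n-1) standard deviation over the pairs
    present for that trait — i.e. over the pair set actually entering the
    model — and the parameters are retained for back-transformation.
    """
    if len(distances) < 2:
        raise ValueError("need at least 2 pairs to standardize")
    out = distances.copy()
    meta = []
    for trait, grp in distances.groupby("trait"):
        for col in ("absolute_raw", "hierarchical_raw"):
            mu = grp[col].mean()
            sd = grp[col].std(ddof=1)
            if sd == 0.0 or not np.isfinite(sd):
                raise ValueError(f"zero variance in {col} for trait {trait}")
            out.loc[grp.index, col.replace("_raw", "_std")] = (grp[col] - mu) / sd
            meta.append({"trait": trait, "predictor": col.replace("_raw", ""), "mean": mu, "sd": sd})
    return TraitDistanceSet(out, pd.DataFrame(meta))
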