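"""Bivariate point-pattern statistics, the toroidal-shift null, and SES.

Two summary statistics describe the pattern of species *j* around a focal
species *i*:

* the bivariate pair correlation function g_ij(r) — a kernel estimate of the
  relative density of j stems at distance r from an i stem (1 under
  independence), with translation edge correction;
* the bivariate nearest-neighbour distribution D_ij(r) — the empirical
  fraction of i stems whose nearest j stem lies within r (no edge
  correction: the identical estimator is applied to observed and null
  patterns, so edge bias cancels in the standardized effect size).

The null model keeps the focal pattern fixed and translates the whole
pattern of species j by a uniform toroidal shift, which breaks cross-species
dependence while preserving each species' internal structure.  Departures
are summarised as the standardized effect size
``z(r) = (S0(r) - mu_null(r)) / sd_null(r)`` and classified as attraction
(z > z_alpha), repulsion (z < -z_alpha) or independence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .synthetic import PointPattern, Window

logger = logging.getLogger(__name__)

__all__ = [
    "SummaryStatistic",
    "NullEnsemble",
    "AssociationRecord",
    "STATISTICS",
    "default_bandwidth",
    "estimate_bivariate_pcf",
    "estimate_nn_distribution",
    "toroidal_shift",
    "null_ensemble",
    "ses",
    "classify_association",
    "ordered_pairs",
    "pairwise_association_analysis",
    "associations_to_frame",
]

STATISTICS = ("pcf", "D")

ATTRACTION = "attraction"
REPULSION = "repulsion"
INDEPENDENCE = "independence"


@dataclass(frozen=True)
class SummaryStatistic:
    name: str
    r: float
    value: float

    def __post_init__(self) -> None:
        if self.name not in STATISTICS:
            raise ValueError(f"unknown statistic {self.name!r}")
        if self.r <= 0:
            raise ValueError("radius must be positive")


@dataclass
class NullEnsemble:
    """Replicate statistic values under the toroidal-shift null."""

    name: str
    r: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 2:
            raise ValueError("null ensemble needs at least 2 replicates")

    @property
    def n_sim(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        # sample (n-1) standard deviation over replicates
        return float(self.values.std(ddof=1))

    @property
    def degenerate(self) -> bool:
        return _is_degenerate(self.sd, self.mean)


def _is_degenerate(sd: float, mean: float) -> bool:
    """Zero null variance up to floating error relative to the mean."""
    return sd <= 1e-12 * max(1.0, abs(mean))


@dataclass(frozen=True)
class AssociationRecord:
    """One ordered species pair x statistic x radius."""

    focal: str
    other: str
    statistic: str
    r: float
    observed: float
    null_mean: float
    null_sd: float
    z: float
    classification: str
    n_sim: int
    degenerate: bool = False


def default_bandwidth(intensity_j: float, r: float) -> float:
    """Epanechnikov bandwidth 0.15 / sqrt(lambda_j), clipped to [0.5 m, r/2]."""
    h = 0.15 / np.sqrt(intensity_j)
    return float(np.clip(h, 0.5, r / 2.0))


def _check_pair(pattern_i: PointPattern, pattern_j: PointPattern, r: float) -> None:
    if pattern_i.window != pattern_j.window:
        raise ValueError("patterns must share the same window")
    w = pattern_i.window
    if r > min(w.width, w.height) / 2.0:
        raise ValueError("r exceeds half the shorter window side")
    if r <= 0:
        raise ValueError("radius must be positive")


def _batch_statistics(
    xi: np.ndarray,
    xj: np.ndarray,
    window: Window,
    radii,
    statistics,
    shifts: np.ndarray,
    bandwidths: dict | None = None,
    chunk: int = 64,
):
    """Evaluate the requested statistics for every toroidal shift of xj.

    Returns ``{(stat, r): values}`` with one value per shift.  A single
    displacement tensor per chunk serves every statistic and radius, which
    is what makes whole-community analyses tractable.
    """
    w, h = window.width, window.height
    area = window.area
    ni, nj = len(xi), len(xj)
    lam_i, lam_j = ni / area, nj / area
    if bandwidths is None:
        bandwidths = {r: default_bandwidth(lam_j, r) for r in radii}
    out = {(s, r): np.empty(len(shifts)) for s in statistics for r in radii}
    for start in range(0, len(shifts), chunk):
        sh = shifts[start : start + chunk]
        xjs_x = (xj[None, :, 0] - window.x_min + sh[:, 0:1]) % w + window.x_min
        xjs_y = (xj[None, :, 1] - window.y_min + sh[:, 1:2]) % h + window.y_min
        dx = xi[None, :, None, 0] - xjs_x[:, None, :]
        dy = xi[None, :, None, 1] - xjs_y[:, None, :]
        dist = np.hypot(dx, dy)
        sl = slice(start, start + len(sh))
        if "pcf" in statistics:
            edge = (w - np.abs(dx)) * (h - np.abs(dy))
            for r in radii:
                bw = bandwidths[r]
                u = (dist - r) / bw
                k = np.where(np.abs(u) < 1.0, 0.75 * (1.0 - u * u) / bw, 0.0)
                total = (k / edge).sum(axis=(1, 2))
                out[("pcf", r)][sl] = total / (2.0 * np.pi * r * lam_i * lam_j)
        if "D" in statistics:
            nnd = dist.min(axis=2)
            for r in radii:
                out[("D", r)][sl] = (nnd <= r).mean(axis=1)
    return out


def estimate_bivariate_pcf(
    pattern_i: PointPattern,
    pattern_j: PointPattern,
    r: float,
    bandwidth: float | None = None,
    correction: str = "translation",
) -> SummaryStatistic:
    """Kernel estimate of the bivariate pair correlation function g_ij(r).

    Sums an Epanechnikov kernel in (pairwise distance - r) over all
    cross-species point pairs, divides by 2*pi*r and the product of
    intensities, with translation edge correction (each pair weighted by the
    reciprocal area over which its displacement is observable).
    """
    if pattern_i.n == 0 or pattern_j.n == 0:
        raise ValueError("pcf undefined for empty patterns (zero intensity)")
    _check_pair(pattern_i, pattern_j, r)
    if correction not in ("translation", "none"):
        raise ValueError("correction must be 'translation' or 'none'")
    win = pattern_i.window
    dx = pattern_i.points[:, None, 0] - pattern_j.points[None, :, 0]
    dy = pattern_i.points[:, None, 1] - pattern_j.points[None, :, 1]
    dist = np.hypot(dx, dy)
    lam_i, lam_j = pattern_i.intensity, pattern_j.intensity
    bw = bandwidth if bandwidth is not None else default_bandwidth(lam_j, r)
    u = (dist - r) / bw
    k = np.where(np.abs(u) < 1.0, 0.75 * (1.0 - u * u) / bw, 0.0)
    if correction == "translation":
        weight = 1.0 / ((win.width - np.abs(dx)) * (win.height - np.abs(dy)))
        total = (k * weight).sum()
    else:
        total = k.sum() / win.area
    value = total / (2.0 * np.pi * r * lam_i * lam_j)
    return SummaryStatistic("pcf", r, float(value))


def estimate_nn_distribution(
    pattern_i: PointPattern, pattern_j: PointPattern, r: float
) -> SummaryStatistic:
    """Empirical D_ij(r): fraction of focal stems with a j stem within r."""
    if pattern_j.n == 0:
        raise ValueError("D undefined: species j pattern is empty")
    if pattern_i.n == 0:
        raise ValueError("D undefined: focal pattern is empty")
    _check_pair(pattern_i, pattern_j, r)
    d = np.hypot(
        pattern_i.points[:, None, 0] - pattern_j.points[None, :, 0],
        pattern_i.points[:, None, 1] - pattern_j.points[None, :, 1],
    )
    nnd = d.min(axis=1)
    return SummaryStatistic("D", r, float((nnd <= r).mean()))


def toroidal_shift(pattern: PointPattern, dx: float, dy: float) -> PointPattern:
    """Translate every point by (dx, dy) with wraparound; window unchanged."""
    shifted = pattern.points + np.array([dx, dy])
    return PointPattern(pattern.window.wrap(shifted), pattern.window)


def null_ensemble(
    pattern_i: PointPattern,
    pattern_j: PointPattern,
    statistic: str,
    r: float,
    n_sim: int,
    seed=None,
    bandwidth: float | None = None,
) -> NullEnsemble:
    """Toroidal-shift null: pattern_i fixed, pattern_j shifted uniformly."""
    if n_sim < 2:
        raise ValueError("n_sim must be >= 2")
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    if pattern_i.n == 0 or pattern_j.n == 0:
        raise ValueError("null ensemble undefined for empty patterns")
    _check_pair(pattern_i, pattern_j, r)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    win = pattern_i.window
    shifts = np.column_stack(
        [rng.uniform(0.0, win.width, n_sim), rng.uniform(0.0, win.height, n_sim)]
    )
    bws = {r: bandwidth} if bandwidth is not None else None
    vals = _batch_statistics(
        pattern_i.points, pattern_j.points, win, [r], [statistic], shifts, bws
    )[(statistic, r)]
    ens = NullEnsemble(statistic, r, vals)
    if ens.degenerate:
        logger.warning("degenerate null ensemble (zero variance) for %s at r=%g", statistic, r)
    return ens


def ses(observed: SummaryStatistic, ensemble: NullEnsemble) -> float:
    """Standardized effect size z = (S0 - mu_null) / sd_null.

    With zero null variance, returns 0 when the observed value equals the
    null mean and signed infinity otherwise (``ensemble.degenerate`` flags
    the case).
    """
    if observed.name != ensemble.name or observed.r != ensemble.r:
        raise ValueError("observed statistic and null ensemble do not match")
    mu, sd = ensemble.mean, ensemble.sd
    if ensemble.degenerate:
        if np.isclose(observed.value, mu):
            return 0.0
        return float(np.sign(observed.value - mu) * np.inf)
    return float((observed.value - mu) / sd)


def classify_association(z: float, alpha: float = 0.05) -> str:
    """Attraction if z > z_alpha, repulsion if z < -z_alpha, else independence.

    ``z_alpha`` is the standard-normal two-sided critical value (1.96 at
    alpha = .05); the inequalities are strict, so z exactly at the critical
    value counts as independence.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    z_crit = norm.ppf(1.0 - alpha / 2.0)
    if z > z_crit:
        return ATTRACTION
    if z < -z_crit:
        return REPULSION
    return INDEPENDENCE


def ordered_pairs(species):
    """All ordered pairs (focal, other) of distinct species."""
    species = list(species)
    return [(i, j) for i in species for j in species if i != j]


def pairwise_association_analysis(
    census: pd.DataFrame,
    window: Window,
    radii=(5.0, 30.0, 50.0),
    statistics=STATISTICS,
    n_sim: int = 999,
    alpha: float = 0.05,
    seed=None,
) -> list[AssociationRecord]:
    """Ordered-pair association analysis for every species pair in a census.

    Each species serves as the focal species in turn (associations may be
    asymmetric), giving n(n-1) ordered pairs per statistic per radius.  For
    one ordered pair, a single stream of toroidal shifts of the non-focal
    pattern feeds all statistics and radii; SES classification is pointwise,
    so the induced correlation between radii is immaterial.
    """
    statistics = tuple(statistics)
    for s in statistics:
        if s not in STATISTICS:
            raise ValueError(f"unknown statistic {s!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    species = sorted(census["species_id"].unique())
    if len(species) < 2:
        logger.warning("fewer than 2 species after filtering; nothing to analyse")
        return []
    coords = {
        sp: census.loc[census["species_id"] == sp, ["x", "y"]].to_numpy(dtype=float)
        for sp in species
    }
    z_crit = norm.ppf(1.0 - alpha / 2.0)
    records: list[AssociationRecord] = []
    for focal, other in ordered_pairs(species):
        xi, xj = coords[focal], coords[other]
        shifts = np.column_stack(
            [rng.uniform(0.0, window.width, n_sim), rng.uniform(0.0, window.height, n_sim)]
        )
        obs = _batch_statistics(xi, xj, window, radii, statistics, np.zeros((1, 2)))
        null = _batch_statistics(xi, xj, window, radii, statistics, shifts)
        for stat in statistics:
            for r in radii:
                s0 = float(obs[(stat, r)][0])
                vals = null[(stat, r)]
                mu = float(vals.mean())
                sd = float(vals.std(ddof=1))
                degenerate = _is_degenerate(sd, mu)
                if degenerate:
                    z = 0.0 if np.isclose(s0, mu) else float(np.sign(s0 - mu) * np.inf)
                else:
                    z = (s0 - mu) / sd
                if z > z_crit:
                    cls = ATTRACTION
                elif z < -z_crit:
                    cls = REPULSION
                else:
                    cls = INDEPENDENCE
                records.append(
                    AssociationRecord(
                        focal, other, stat, float(r), s0, mu, sd, z, cls, n_sim, degenerate
                    )
                )
    return records


def associations_to_frame(records) -> pd.DataFrame:
    """AssociationRecord list -> tidy DataFrame (the associations CSV layout)."""
    return pd.DataFrame(
        {
            "focal_id": [a.focal for a in records],
            "other_id": [a.other for a in records],
            "statistic": [a.statistic for a in records],
            "r": [a.r for a in records],
            "observed": [a.observed for a in records],
            "null_mean": [a.null_mean for a in records],
            "null_sd": [a.null_sd for a in records],
            "z": [a.z for a in records],
            "class": [a.classification for a in records],
            "degenerate_flag": [a.degenerate for a in records],
        }
    )
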