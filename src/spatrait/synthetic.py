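"""Synthetic mapped communities with known assembly mechanisms.

Generates stem-mapped multi-species point patterns plus a species-level
trait table under four generative scenarios:

``neutral``
    Every species is an independent Thomas cluster process; traits carry no
    spatial information.  Used to calibrate the null-model machinery.
``filtering``
    A smooth sinusoidal habitat covariate spans the plot.  Each species
    prefers the habitat value matching its position on a latent trait axis,
    and candidate stems are thinned with probability increasing in the
    squared mismatch between local habitat and the species' preference.
    Species with similar traits therefore co-locate.
``hierarchical``
    Dominant species form large stands whose patch-scale, density-weighted
    crowding defines a competitive pressure field; candidate stems are
    thinned with probability increasing in their own competitive inferiority
    times the local pressure (asymmetric, rank-graded disadvantage).
    Low-ranked species survive mainly in the shared competition shadows, so
    co-occurrence becomes assortative by competitive rank.
``limiting_similarity``
    Candidate stems are thinned with probability increasing in the local
    density of heterospecific neighbours with *similar* trait values,
    producing spatial repulsion between functionally similar species.

All randomness flows through one :class:`numpy.random.Generator` seeded from
the scenario config, so an identical config reproduces byte-identical
tables.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "Window",
    "PointPattern",
    "ScenarioConfig",
    "SCENARIOS",
    "TRAIT_COLUMNS",
    "simulate_poisson_pattern",
    "simulate_thomas_pattern",
    "simulate_community",
    "habitat_field",
    "write_community",
    "read_census",
    "read_traits",
    "read_window",
]

TRAIT_COLUMNS = ["LA", "SLA", "LDMC", "WD", "WDMC", "H_max"]

SCENARIOS = ("neutral", "filtering", "hierarchical", "limiting_similarity")


# ---------------------------------------------------------------------------
# Spatial containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Window:
    """Rectangular observation window, coordinates in metres."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("window must have positive extent on both axes")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, x, y) -> np.ndarray:
        """Closed-bound membership test (vectorised)."""
        x = np.asarray(x)
        y = np.asarray(y)
        return (
            (x >= self.x_min)
            & (x <= self.x_max)
            & (y >= self.y_min)
            & (y <= self.y_max)
        )

    def wrap(self, points: np.ndarray) -> np.ndarray:
        """Wrap coordinates toroidally back into the window."""
        pts = np.array(points, dtype=float, copy=True)
        pts[:, 0] = (pts[:, 0] - self.x_min) % self.width + self.x_min
        pts[:, 1] = (pts[:, 1] - self.y_min) % self.height + self.y_min
        return pts

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Window":
        return cls(d["x_min"], d["x_max"], d["y_min"], d["y_max"])


@dataclass(frozen=True)
class PointPattern:
    """Locations of one species' stems inside a rectangular window."""

    points: np.ndarray
    window: Window

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "points", pts)
        if pts.size and not self.window.contains(pts[:, 0], pts[:, 1]).all():
            raise ValueError("points must lie inside the window (closed bounds)")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def intensity(self) -> float:
        return self.n / self.window.area


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Elementary point processes
# ---------------------------------------------------------------------------


def simulate_poisson_pattern(intensity: float, window: Window, seed=None) -> PointPattern:
    """Homogeneous Poisson process with ``intensity`` points per m²."""
    if intensity < 0:
        raise ValueError("intensity must be non-negative")
    rng = _as_rng(seed)
    n = rng.poisson(intensity * window.area)
    x = rng.uniform(window.x_min, window.x_max, n)
    y = rng.uniform(window.y_min, window.y_max, n)
    return PointPattern(np.column_stack([x, y]), window)


def simulate_thomas_pattern(
    kappa: float, sigma: float, mu_off: float, window: Window, seed=None
) -> PointPattern:
    """Thomas cluster process on the torus.

    Parents are Poisson(``kappa`` × area) and uniform; each parent receives a
    Poisson(``mu_off``) number of offspring displaced by an isotropic
    Gaussian with standard deviation ``sigma``.  Offspring falling outside
    the window are wrapped toroidally, which keeps the process exactly
    homogeneous (no edge-induced intensity gradient).  Expected total count
    is ``kappa * mu_off * area``.
    """
    if kappa <= 0 or sigma <= 0 or mu_off <= 0:
        raise ValueError("kappa, sigma and mu_off must all be positive")
    rng = _as_rng(seed)
    n_parents = rng.poisson(kappa * window.area)
    px = rng.uniform(window.x_min, window.x_max, n_parents)
    py = rng.uniform(window.y_min, window.y_max, n_parents)
    counts = rng.poisson(mu_off, n_parents)
    total = int(counts.sum())
    if total == 0:
        return PointPattern(np.empty((0, 2)), window)
    cx = np.repeat(px, counts) + rng.normal(0.0, sigma, total)
    cy = np.repeat(py, counts) + rng.normal(0.0, sigma, total)
    return PointPattern(window.wrap(np.column_stack([cx, cy])), window)


def _thomas_fixed_count(
    n: int, kappa: float, sigma: float, window: Window, rng: np.random.Generator
) -> np.ndarray:
    """Thomas-type clustered pattern conditioned on exactly ``n`` points.

    Parents are Poisson(kappa × area) (at least one); the ``n`` offspring are
    assigned to parents uniformly at random, then Gaussian-displaced and
    wrapped.  Conditioning on the total keeps per-species abundance exactly
    at the configured value before any thinning.
    """
    n_parents = max(1, int(rng.poisson(kappa * window.area)))
    px = rng.uniform(window.x_min, window.x_max, n_parents)
    py = rng.uniform(window.y_min, window.y_max, n_parents)
    assign = rng.integers(0, n_parents, n)
    pts = np.column_stack(
        [px[assign] + rng.normal(0.0, sigma, n), py[assign] + rng.normal(0.0, sigma, n)]
    )
    return window.wrap(pts)


# ---------------------------------------------------------------------------
# Scenario configuration
# ---------------------------------------------------------------------------

# Species-mean trait generator: log-normal marginals with a shared latent
# axis f (resource acquisition / stature).  (log-mean, log-sd, loading sign)
# per trait; acquisitive traits (LA, SLA, H_max) load positively, tissue
# density traits (LDMC, WD, WDMC) negatively.
_TRAIT_GENERATOR = {
    "LA": (math.log(30.0), 0.60, +1.0),
    "SLA": (math.log(120.0), 0.35, +1.0),
    "LDMC": (math.log(0.40), 0.25, -1.0),
    "WD": (math.log(0.55), 0.20, -1.0),
    "WDMC": (math.log(0.50), 0.15, -1.0),
    "H_max": (math.log(15.0), 0.40, +1.0),
}


@dataclass
class ScenarioConfig:
    """Generative parameters for one synthetic assembly mechanism.

    Defaults describe a mid-sized mapped community: 20 species with 150
    candidate stems each in a 250 × 250 m window, within-species clustering
    from ~12 cluster parents per species with 15 m offspring dispersal, and
    strongly expressed (but bounded) biotic interactions.
    """

    scenario: str
    n_species: int = 20
    abundance: int = 150
    window: Window = field(default_factory=lambda: Window(0.0, 250.0, 0.0, 250.0))
    kappa: float = 2e-4          # cluster-parent intensity per m²
    sigma: float = 15.0          # offspring dispersal sd, m
    mu_off: float | None = None  # informational; implied by abundance/(kappa*area)
    interaction_strength: float = 4.0   # dimensionless thinning strength
    max_removal: float = 0.9     # cap on per-stem removal probability
    neighbor_sigma: float = 10.0 # spatial interaction kernel sd, m
    trait_kernel_sd: float = 0.5 # latent-trait similarity kernel sd (limiting similarity)
    habitat_wavelength: float = 125.0  # m, sinusoidal habitat covariate
    factor_loading: float = 0.6  # correlation of each log-trait with the latent axis
    sapling_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        if self.n_species < 1 or self.abundance < 1:
            raise ValueError("n_species and abundance must be >= 1")
        if self.sigma <= 0 or self.kappa <= 0 or self.neighbor_sigma <= 0:
            raise ValueError("kappa, sigma and neighbor_sigma must be positive")
        if self.interaction_strength < 0:
            raise ValueError("interaction_strength must be >= 0")
        if not 0.0 <= self.max_removal < 1.0:
            raise ValueError("max_removal must be in [0, 1)")


def habitat_field(x, y, wavelength: float, phase_x: float = 0.0, phase_y: float = 0.0):
    """Smooth sinusoidal habitat covariate mapped to [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    raw = 0.5 * (
        np.sin(2.0 * np.pi * x / wavelength + phase_x)
        + np.sin(2.0 * np.pi * y / wavelength + phase_y)
    )
    return 0.5 * (raw + 1.0)


def _species_traits(config: ScenarioConfig, rng: np.random.Generator):
    """Latent axis f ~ N(0,1) per species plus six correlated log-normal traits."""
    s = config.n_species
    f = rng.normal(size=s)
    rho = config.factor_loading
    rows = {}
    for trait, (mu, sd, sign) in _TRAIT_GENERATOR.items():
        eps = rng.normal(size=s)
        log_t = mu + sd * (sign * rho * f + math.sqrt(1.0 - rho**2) * eps)
        rows[trait] = np.exp(log_t)
    return f, rows


def _strategy_axis(species_ids, trait_values) -> np.ndarray:
    """Realized integrated strategy axis of the generated trait table.

    The biotic/abiotic interactions act on the community's own leading trait
    axis (PCA axis 1 of the species x trait matrix, standardized to unit
    variance) rather than on the unobservable latent factor, so the
    mechanism trait is exactly recoverable from the trait table alone.
    """
    from .trait_distances import integrated_trait_scores  # deferred: avoids cycle

    tab = pd.DataFrame({"species_id": species_ids})
    for trait in TRAIT_COLUMNS:
        tab[trait] = trait_values[trait]
    scores, _, _ = integrated_trait_scores(tab)
    s = scores.to_numpy()
    return (s - s.mean()) / s.std(ddof=0)


def _gaussian_crowding(points, species_idx, f, sigma_n, trait_kernel_sd):
    """Per-candidate heterospecific crowding sums used by the thinning rules.

    Returns (total, dominance, similar): Gaussian-kernel-weighted counts of
    all heterospecific neighbours, of neighbours weighted by their
    competitive dominance (cubed rank percentile, so the field is sourced
    mainly by the top-ranked species), and of neighbours weighted by
    strategy-axis similarity.
    """
    n = len(points)
    total = np.zeros(n)
    dominance = np.zeros(n)
    similar = np.zeros(n)
    tree = cKDTree(points)
    pairs = tree.query_pairs(r=3.5 * sigma_n, output_type="ndarray")
    if len(pairs) == 0:
        return total, dominance, similar
    a, b = pairs[:, 0], pairs[:, 1]
    hetero = species_idx[a] != species_idx[b]
    a, b = a[hetero], b[hetero]
    d2 = ((points[a] - points[b]) ** 2).sum(axis=1)
    w = np.exp(-d2 / (2.0 * sigma_n**2))
    fa, fb = f[species_idx[a]], f[species_idx[b]]
    dom_a, dom_b = norm.cdf(fa) ** 3, norm.cdf(fb) ** 3
    np.add.at(total, a, w)
    np.add.at(total, b, w)
    np.add.at(dominance, a, w * dom_b)
    np.add.at(dominance, b, w * dom_a)
    ws = w * np.exp(-((fa - fb) ** 2) / (2.0 * trait_kernel_sd**2))
    np.add.at(similar, a, ws)
    np.add.at(similar, b, ws)
    return total, dominance, similar


def _removal_probability(config: ScenarioConfig, exposure: np.ndarray) -> np.ndarray:
    """Saturating removal curve p = max_removal * (1 - exp(-s * exposure))."""
    s = config.interaction_strength
    return config.max_removal * (1.0 - np.exp(-s * exposure))


def simulate_community(config: ScenarioConfig):
    """Generate one community under ``config``.

    Returns ``(census, traits, labels)`` where ``census`` is a stem table
    (stem_id, species_id, x, y, dbh, height), ``traits`` a species-level
    trait table, and ``labels`` a ground-truth dict (scenario, per-species
    latent trait values and ranks, candidate and retained counts).
    """
    rng = np.random.default_rng(config.seed)
    win = config.window
    species_ids = [f"sp{k + 1:02d}" for k in range(config.n_species)]

    f_latent, trait_values = _species_traits(config, rng)
    # Interaction trait: the realized leading strategy axis of the community.
    f = _strategy_axis(species_ids, trait_values)

    # Candidate stems: exactly `abundance` per species, clustered.  Real
    # communities differ widely in aggregation, so per-species cluster
    # parameters scatter (log-uniformly) around the configured values.
    # Under hierarchical competition, dominant species additionally
    # aggregate into fewer, larger stands (monodominance), which is what
    # makes their competitive pressure spatially coherent.
    kappa_s = config.kappa * np.exp(rng.uniform(-1.2, 1.2, config.n_species))
    if config.scenario == "hierarchical":
        kappa_s = kappa_s * np.exp(-norm.cdf(f))
    sigma_s = config.sigma * np.exp(rng.uniform(-0.5, 0.5, config.n_species))
    pts = np.concatenate(
        [
            _thomas_fixed_count(config.abundance, kappa_s[k], sigma_s[k], win, rng)
            for k in range(config.n_species)
        ]
    )
    sp_idx = np.repeat(np.arange(config.n_species), config.abundance)

    if config.scenario == "neutral":
        p_remove = np.zeros(len(pts))
    elif config.scenario == "filtering":
        phase_x, phase_y = rng.uniform(0.0, 2.0 * np.pi, 2)
        env = habitat_field(pts[:, 0], pts[:, 1], config.habitat_wavelength, phase_x, phase_y)
        preference = norm.cdf(f)[sp_idx]
        # 1/6 is the a-priori mean squared mismatch of two independent
        # uniforms; it makes interaction_strength dimensionless.
        p_remove = _removal_probability(config, (env - preference) ** 2 / (1.0 / 6.0))
    elif config.scenario == "hierarchical":
        # One-sided, rank-graded exclusion from the dominants' home ranges.
        # The pressure field is the patch-scale (3.5x interaction kernel)
        # crowding by high-ranked neighbours; areas below its lower quartile
        # are competition shadows where any species persists.  A stem's
        # removal risk is its squared inferiority percentile (top-ranked
        # species are insensitive) times the excess pressure, so inferior
        # species are displaced into shared refuges: co-occurrence becomes
        # assortative by competitive rank.
        _, pressure, _ = _gaussian_crowding(
            pts, sp_idx, f, 3.5 * config.neighbor_sigma, config.trait_kernel_sd
        )
        q25 = float(np.quantile(pressure, 0.25))
        relief = np.maximum(pressure - q25, 0.0)
        exposure = norm.cdf(-f)[sp_idx] ** 2 * relief / max(relief.mean(), 1e-12)
        p_remove = _removal_probability(config, exposure)
    else:  # limiting_similarity
        # Exposure is similarity-weighted crowding relative to the mean
        # *overall* crowding, so removal stays concentrated where trait
        # twins actually meet instead of blanket-thinning species with many
        # similar competitors.
        total, _, similar = _gaussian_crowding(
            pts, sp_idx, f, config.neighbor_sigma, config.trait_kernel_sd
        )
        p_remove = _removal_probability(
            config, similar / max(total.mean(), 1e-12)
        )

    keep = rng.random(len(pts)) >= p_remove
    pts, sp_idx = pts[keep], sp_idx[keep]

    n_stems = len(pts)
    # DBH mixture populating both life-stage classes (1-3 cm and >10 cm),
    # independent of traits.
    is_sapling = rng.random(n_stems) < config.sapling_fraction
    dbh = np.where(
        is_sapling,
        rng.uniform(1.0, 3.0, n_stems),
        rng.uniform(10.0, 60.0, n_stems),
    )
    dbh = np.round(dbh, 2)
    # Simple asymptotic height allometry toward the species' H_max.
    h_pot = trait_values["H_max"][sp_idx]
    height = h_pot * dbh / (dbh + 5.0) * np.exp(rng.normal(0.0, 0.05, n_stems))
    height = np.round(height, 2)

    census = pd.DataFrame(
        {
            "stem_id": np.arange(1, n_stems + 1),
            "species_id": np.array(species_ids)[sp_idx],
            "x": np.round(pts[:, 0], 3),
            "y": np.round(pts[:, 1], 3),
            "dbh": dbh,
            "height": height,
        }
    )
    traits = pd.DataFrame({"species_id": species_ids})
    for trait in TRAIT_COLUMNS:
        traits[trait] = np.round(trait_values[trait], 4)

    retained = census["species_id"].value_counts().reindex(species_ids, fill_value=0)
    labels = {
        "scenario": config.scenario,
        "seed": config.seed,
        "latent_trait": dict(zip(species_ids, f.tolist())),
        "latent_factor": dict(zip(species_ids, f_latent.tolist())),
        "trait_rank": dict(
            zip(species_ids, (np.argsort(np.argsort(f)) + 1).tolist())
        ),
        "candidates_per_species": config.abundance,
        "retained_per_species": retained.to_dict(),
    }
    logger.info(
        "simulated %s community: %d species, %d/%d stems retained",
        config.scenario,
        config.n_species,
        n_stems,
        config.n_species * config.abundance,
    )
    return census, traits, labels


# ---------------------------------------------------------------------------
# Plain-text I/O
# ---------------------------------------------------------------------------


def write_community(census, traits, window, outdir, prefix="community") -> dict:
    """Write census and trait CSVs plus a window JSON sidecar; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "census": outdir / f"{prefix}_census.csv",
        "traits": outdir / f"{prefix}_traits.csv",
        "window": outdir / f"{prefix}_window.json",
    }
    census.to_csv(paths["census"], index=False)
    traits.to_csv(paths["traits"], index=False)
    paths["window"].write_text(json.dumps(window.to_dict(), indent=2))
    return {k: str(v) for k, v in paths.items()}


def read_census(path, columns: dict | None = None) -> pd.DataFrame:
    """Read a census CSV; ``columns`` maps foreign headers to the standard
    ones (species_id, x, y, dbh[, height, stem_id])."""
    df = pd.read_csv(path)
    if columns:
        df = df.rename(columns=columns)
    required = {"species_id", "x", "y", "dbh"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"census file missing columns: {sorted(missing)}")
    return df


def read_traits(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "species_id" not in df.columns:
        raise ValueError("trait file must contain a species_id column")
    if df["species_id"].duplicated().any():
        raise ValueError("trait file has duplicated species_id rows")
    return df


def read_window(path) -> Window:
    return Window.from_dict(json.loads(Path(path).read_text()))
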