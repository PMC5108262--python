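"""Virtual landscapes with known ground truth.

Generates the two inputs the pipeline needs — an environment table and a
binary occurrence matrix — from an explicit generative model, so every
stage can be tested against a known truth without any external data.

Environment model
-----------------
Each site gets ``n_gradients`` independent standard-normal latent gradient
values (think temperature, moisture, ...).  The ``n_observed_vars``
covariates are noisy linear readouts of the gradients, deliberately
*unequal* in strength: earlier gradients get more variables and cleaner
readouts, the way energy-related variables dominate real climate stacks.
This gives the correlation matrix well-separated leading eigenvalues — one
Kaiser-significant component per gradient — so PCA components align with
gradients instead of rotating arbitrarily inside tied eigenvalue blocks.
Some variables carry a weak secondary loading on a neighbouring gradient,
mimicking covariates that track two environmental axes at once.

Species model
-------------
Each species has a Gaussian (bell-shaped) niche per gradient — optimum
mu_g, breadth sigma_g — and a maximum occupancy h in (0, 1].  Its
suitability at a site is the product Gaussian term
g(x) = exp(-1/2 * sum_g ((x_g - mu_g) / sigma_g)^2).  Two guilds:

* restricted species (fraction ``restricted_fraction``): grouped into
  ``n_endemism_centers`` clusters ("centers of endemism").  Each cluster
  centre sits ``rarity_shift`` SDs up the first gradient — its suitable
  environment is genuinely scarce — and at a random position on the other
  gradients, so different clusters occupy different corners of environment
  space.  Species scatter tightly around their cluster centre with
  moderately narrow niches on every gradient.
* widespread species: broad niches centred near typical conditions.

This mirrors the structure that makes rarity-weighted richness mappable in
real landscapes: a dominant environmental axis (elevation/energy) along
which restricted species concentrate, with compositional turnover among
the rare-environment sites — each rarity hotspot hosts its own endemics,
so hotspots complement one another rather than repeating the same species.

Occupancy
---------
Presence is an independent Bernoulli draw per site and species with

    p = d * h * g(x) + (1 - d) * h * g_bar,

where g_bar is the species' landscape-mean Gaussian term and d in [0, 1]
is the environmental-determinism dial.  At d=1 occupancy is a pure
function of environment; at d=0 it is spatially uniform noise — while the
species' *expected* prevalence is identical at every d, so rarity
structure and environmental signal are independently tunable.  Right-
skewed range sizes (many narrow-range species, few widespread ones) emerge
from the restricted guild and the lognormal-like spread of mean
suitability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._rng import child_seed
from .core_data import EnvironmentTable, OccurrenceMatrix
from .errors import ConfigError, DataError
from .rwr import SiteScores, compute_rwr, rarity_weights

__all__ = [
    "LandscapeSpec",
    "SpeciesNiche",
    "LandscapeTruth",
    "generate_environment",
    "occupancy_probability",
    "sample_occurrences",
]

_ENV_KEY = 0
_NICHE_KEY = 1
_DRAW_KEY = 2


@dataclass(frozen=True)
class LandscapeSpec:
    """Parameters of a virtual landscape.

    Defaults describe a mid-sized atlas: 1,000 sites, 300 species driven by
    6 environmental gradients observed through 18 noisy covariates, 70%
    restricted species concentrated 1.5 SDs up the first gradient, with
    strong environmental determinism (d = 0.9).
    """

    n_sites: int = 1000
    n_gradients: int = 6
    n_observed_vars: int = 18
    n_species: int = 300
    restricted_fraction: float = 0.7  # share of narrow-range species
    n_endemism_centers: int = 12  # clusters of co-occurring restricted spp.
    rarity_shift: float = 1.5  # cluster offset on the rarity axis, gradient SDs
    restricted_breadth: float = 0.7  # sigma on the rarity axis
    secondary_breadth: float = 1.1  # sigma on the remaining axes (restricted)
    broad_breadth: float = 3.0  # sigma for widespread species
    niche_breadth_spread: float = 0.2  # lognormal spread multiplier on sigmas
    prevalence_alpha: float = 8.0  # Beta(a, b) for max occupancy h: high h
    prevalence_beta: float = 2.0   # -> presence near-certain where suitable
    mixing_noise: float = 0.15  # base sd of observation noise on covariates
    determinism: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sites", "n_gradients", "n_observed_vars", "n_species"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.n_observed_vars < self.n_gradients:
            raise ConfigError("n_observed_vars must be >= n_gradients")
        if not 0.0 <= self.determinism <= 1.0:
            raise ConfigError(f"determinism must be in [0, 1], got {self.determinism}")
        if not 0.0 <= self.restricted_fraction <= 1.0:
            raise ConfigError("restricted_fraction must be in [0, 1]")
        if self.n_endemism_centers < 1:
            raise ConfigError("n_endemism_centers must be >= 1")
        for name in ("restricted_breadth", "secondary_breadth", "broad_breadth"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.niche_breadth_spread < 0 or self.mixing_noise < 0:
            raise ConfigError("spread and noise parameters must be >= 0")


@dataclass(frozen=True)
class SpeciesNiche:
    """Gaussian niche: per-gradient optimum and breadth, plus max occupancy."""

    optima: np.ndarray  # mu_g
    breadths: np.ndarray  # sigma_g > 0
    max_occupancy: float  # h in (0, 1]

    def __post_init__(self) -> None:
        optima = np.asarray(self.optima, dtype=float)
        breadths = np.asarray(self.breadths, dtype=float)
        if optima.shape != breadths.shape:
            raise ConfigError("optima and breadths must have equal length")
        if not (breadths > 0).all():
            raise ConfigError("niche breadths must be positive")
        if not 0 < self.max_occupancy <= 1:
            raise ConfigError(f"max occupancy must be in (0, 1], got {self.max_occupancy}")
        object.__setattr__(self, "optima", optima)
        object.__setattr__(self, "breadths", breadths)

    def suitability(self, gradients: np.ndarray) -> np.ndarray:
        """Product Gaussian term g(x) per site; gradients is (sites, g)."""
        g = np.atleast_2d(np.asarray(gradients, dtype=float))
        z = (g - self.optima) / self.breadths
        return np.exp(-0.5 * (z**2).sum(axis=1))


@dataclass(frozen=True)
class LandscapeTruth:
    """Everything a recovery test needs: the latent gradients, the niches,
    the occupancy probabilities, and the realized full-landscape RWR."""

    gradients: np.ndarray  # site x gradient
    niches: tuple  # SpeciesNiche per retained species
    probabilities: np.ndarray  # site x species Bernoulli p
    true_rwr: SiteScores


def _site_ids(n: int) -> np.ndarray:
    width = len(str(n - 1))
    return np.array([f"s{i:0{width}d}" for i in range(n)], dtype=object)


def _species_ids(n: int) -> np.ndarray:
    width = len(str(n - 1))
    return np.array([f"sp{i:0{width}d}" for i in range(n)], dtype=object)


def _allocate_vars(n_vars: int, n_gradients: int) -> list[int]:
    """Primary gradient per variable, front-loading earlier gradients.

    Every gradient gets at least two variables when the pool allows (a
    lone variable cannot lift its component's eigenvalue above 1), and the
    surplus is dealt to earlier gradients first so gradient strengths are
    strictly unequal.
    """
    base = 2 if n_vars >= 2 * n_gradients else 1
    counts = [base] * n_gradients
    surplus = n_vars - base * n_gradients
    # triangular deal (0; 0,1; 0,1,2; ...): front-loads earlier gradients so
    # block sizes, hence eigenvalues, come out strictly unequal at the top
    deal = [g for width in range(1, n_gradients + 1) for g in range(width)]
    i = 0
    while surplus > 0:
        counts[deal[i % len(deal)]] += 1
        i += 1
        surplus -= 1
    return [g for g, k in enumerate(counts) for _ in range(k)]


def generate_environment(spec: LandscapeSpec) -> tuple[EnvironmentTable, np.ndarray]:
    """Draw latent gradients and the observed covariate table.

    Variables are allocated to gradients unequally (earlier gradients get
    more variables) and observation noise grows with gradient index, so
    the leading PCA eigenvalues are well separated and components align
    with gradients.  Within a gradient's block, every second variable adds
    a weak loading on the next gradient.  Returns the table plus the
    latent site-by-gradient matrix for truth-checking.
    """
    rng = np.random.default_rng(child_seed(spec.seed, _ENV_KEY))
    gradients = rng.standard_normal((spec.n_sites, spec.n_gradients))
    primaries = _allocate_vars(spec.n_observed_vars, spec.n_gradients)
    values = np.empty((spec.n_sites, spec.n_observed_vars))
    seen: dict[int, int] = {}
    for j, primary in enumerate(primaries):
        rank = seen.get(primary, 0)
        seen[primary] = rank + 1
        x = gradients[:, primary].copy()
        if rank % 2 == 1 and spec.n_gradients > 1:
            secondary = (primary + 1) % spec.n_gradients
            x += 0.3 * gradients[:, secondary]
        noise_sd = spec.mixing_noise * (1.0 + 0.6 * primary)
        if noise_sd > 0:
            x += noise_sd * rng.standard_normal(spec.n_sites)
        values[:, j] = x
    names = np.array(
        [f"var{j:02d}_g{p}" for j, p in enumerate(primaries)], dtype=object
    )
    env = EnvironmentTable(_site_ids(spec.n_sites), names, values)
    return env, gradients


def occupancy_probability(
    niche: SpeciesNiche, gradients: np.ndarray, d: float
) -> np.ndarray:
    """Per-site presence probability under the determinism mixture.

    p = d * h * g(x) + (1 - d) * h * g_bar, with g_bar the mean of g over
    the supplied sites: at d=0 every site gets the same probability and the
    species' expected prevalence matches the d=1 case exactly.
    """
    if not 0.0 <= d <= 1.0:
        raise ConfigError(f"determinism must be in [0, 1], got {d}")
    g = niche.suitability(gradients)
    g_bar = g.mean()
    return niche.max_occupancy * (d * g + (1.0 - d) * g_bar)


def _draw_niches(spec: LandscapeSpec, rng: np.random.Generator) -> list[SpeciesNiche]:
    """Sample the species pool: clustered restricted and widespread guilds."""
    g = spec.n_gradients
    centers = np.empty((spec.n_endemism_centers, g))
    centers[:, 0] = rng.normal(spec.rarity_shift, 0.4, spec.n_endemism_centers)
    if g > 1:
        centers[:, 1:] = rng.normal(0.0, 1.2, (spec.n_endemism_centers, g - 1))
    niches = []
    for _ in range(spec.n_species):
        spread = np.exp(rng.normal(0.0, spec.niche_breadth_spread, size=g))
        if rng.random() < spec.restricted_fraction:
            c = int(rng.integers(spec.n_endemism_centers))
            optima = centers[c] + rng.normal(0.0, 0.35, size=g)
            breadths = np.full(g, spec.secondary_breadth)
            breadths[0] = spec.restricted_breadth
        else:
            optima = rng.normal(0.0, 1.0, size=g)
            breadths = np.full(g, spec.broad_breadth)
        h = float(rng.beta(spec.prevalence_alpha, spec.prevalence_beta))
        niches.append(
            SpeciesNiche(optima, breadths * spread, max_occupancy=max(h, 1e-3))
        )
    return niches


def sample_occurrences(
    spec: LandscapeSpec,
) -> tuple[OccurrenceMatrix, EnvironmentTable, LandscapeTruth]:
    """Generate a full virtual landscape: (occurrences, environment, truth).

    Presences are independent Bernoulli draws from the niche model.  A
    species that ends up with zero presences is redrawn up to 10 times
    (new Bernoulli draws, same niche) and dropped with a warning if still
    empty — full-landscape matrices must not contain ghost species.
    """
    env, gradients = generate_environment(spec)
    niche_rng = np.random.default_rng(child_seed(spec.seed, _NICHE_KEY))
    draw_rng = np.random.default_rng(child_seed(spec.seed, _DRAW_KEY))
    niches = _draw_niches(spec, niche_rng)

    probs = np.column_stack(
        [occupancy_probability(nc, gradients, spec.determinism) for nc in niches]
    )
    presence = (draw_rng.random(probs.shape) < probs).astype(np.int8)
    for j in range(spec.n_species):
        tries = 0
        while presence[:, j].sum() == 0 and tries < 10:
            presence[:, j] = (draw_rng.random(spec.n_sites) < probs[:, j]).astype(np.int8)
            tries += 1
    keep = presence.sum(axis=0) > 0
    n_dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise DataError(
            "all species empty after retries: prevalence parameters too low"
        )
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} species with no presences after 10 redraws",
            stacklevel=2,
        )
    occ = OccurrenceMatrix(
        _site_ids(spec.n_sites), _species_ids(spec.n_species)[keep], presence[:, keep]
    )
    true_rwr = compute_rwr(occ, rarity_weights(occ))
    truth = LandscapeTruth(
        gradients=gradients,
        niches=tuple(nc for nc, k in zip(niches, keep) if k),
        probabilities=probs[:, keep],
        true_rwr=true_rwr,
    )
    return occ, env, truth
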