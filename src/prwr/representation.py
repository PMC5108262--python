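"""Species-accumulation curves and the Species Accumulation Index (SAI).

A prioritization is judged by how fast it accumulates species: rank sites,
add them one at a time, and count the distinct species represented after k
sites (S_k).  Three curves enter the comparison:

* the surrogate curve S — sites in descending order of a score (PRWR);
* the optimal curve O — the best achievable representation for each k,
  approximated by greedy maximum-coverage (each step adds the site
  contributing the most unrepresented species) and, on small instances,
  computed exactly by exhaustive subset enumeration;
* the random baseline R — the exact expected number of species in k sites
  drawn uniformly without replacement, from the hypergeometric absence
  probability: R_k = sum_j [1 - C(N - c_j, k) / C(N, k)].

The Species Accumulation Index at step k is

    SAI_k = (S_k - R_k) / (O_k - R_k)

1 means the surrogate matched optimal selection, 0 means it did no better
than random, negative means worse than random.  The reported value is the
unweighted mean of SAI_k over a set of top fractions of the landscape
(default: 5%, 10%, ..., 50% of sites), the region prioritization decisions
actually concern.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core_data import OccurrenceMatrix, round_half_up
from .errors import CapabilityError, ConsistencyError, DataError, EvaluationError
from .rwr import SiteScores, compute_rwr, rarity_weights

__all__ = [
    "AccumulationCurve",
    "SaiValue",
    "accumulation_curve",
    "greedy_optimal_curve",
    "exact_optimal_curve",
    "expected_random_curve",
    "monte_carlo_random_curve",
    "sai",
    "DEFAULT_FRACTIONS",
]

DEFAULT_FRACTIONS: tuple = (5, 10, 15, 20, 25, 30, 35, 40, 45, 50)

_EPS = 1e-9


@dataclass(frozen=True)
class AccumulationCurve:
    """Cumulative distinct-species counts along an ordered site sequence.

    ``S_k[k-1]`` is the species count after the first k sites.  For the
    analytic random baseline and the exact optimum there is no single site
    ordering, so ``ordered_sites`` is empty.  ``n_sites``/``n_species``
    identify the landscape so curves from different matrices cannot be
    mixed in an SAI.
    """

    ordered_sites: tuple
    S_k: np.ndarray
    kind: Literal["surrogate", "optimal", "random_expected"]
    n_sites: int
    n_species: int

    def __post_init__(self) -> None:
        s = np.asarray(self.S_k, dtype=float)
        if s.size == 0:
            raise DataError("empty accumulation curve")
        if np.any(np.diff(s) < -1e-9):
            raise DataError("S_k must be non-decreasing")
        if s[-1] > self.n_species + 1e-9:
            raise DataError("S_k exceeds total species count")
        object.__setattr__(self, "S_k", s)
        object.__setattr__(self, "ordered_sites", tuple(self.ordered_sites))

    def __len__(self) -> int:
        return len(self.S_k)

    def at(self, k: int) -> float:
        if not 1 <= k <= len(self.S_k):
            raise DataError(f"step k={k} outside curve range 1..{len(self.S_k)}")
        return float(self.S_k[k - 1])

    def to_csv(self, path: str | Path) -> None:
        sites = list(self.ordered_sites) or [""] * len(self.S_k)
        pd.DataFrame(
            {"k": np.arange(1, len(self.S_k) + 1), "site_id": sites, "S_k": self.S_k}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class SaiValue:
    """Per-step SAI values and their unweighted mean.

    Steps where the optimal and random curves coincide (O_k - R_k below
    1e-9) carry no information and are skipped.
    """

    sai_k: dict
    mean_sai: float
    evaluated_steps: tuple


def _cumulative_species(occ: OccurrenceMatrix, order: np.ndarray) -> np.ndarray:
    """S_k for sites taken in ``order`` (row indices), counted against occ."""
    presence = occ.presence[order]
    occupied = presence.any(axis=0)
    first_row = np.argmax(presence[:, occupied], axis=0)
    new_at_step = np.bincount(first_row, minlength=len(order))
    return np.cumsum(new_at_step).astype(float)


def accumulation_curve(
    occ: OccurrenceMatrix, scores: SiteScores, seed: int = 0
) -> AccumulationCurve:
    """Accumulate sites in descending score order.

    Ties are broken by a seeded shuffle (so repeated replicates sample tie
    orderings fairly) and then by site id for full determinism.  S_k is
    counted against the full matrix, whatever subset the scores were
    trained on.
    """
    missing = [s for s in map(str, occ.site_ids) if s not in scores.scores]
    if missing:
        raise ConsistencyError(f"sites without scores: {missing[:5]}")
    if len(scores) != occ.n_sites:
        extra = sorted(set(scores.scores) - set(map(str, occ.site_ids)))
        raise ConsistencyError(f"scores for unknown sites: {extra[:5]}")
    vals = scores.as_array(list(map(str, occ.site_ids)))
    rng = np.random.default_rng(seed)
    jitter = rng.permutation(occ.n_sites)
    # lexsort: last key is primary
    order = np.lexsort((np.arange(occ.n_sites), jitter, -vals))
    return AccumulationCurve(
        ordered_sites=tuple(str(s) for s in occ.site_ids[order]),
        S_k=_cumulative_species(occ, order),
        kind="surrogate",
        n_sites=occ.n_sites,
        n_species=occ.n_species,
    )


def greedy_optimal_curve(occ: OccurrenceMatrix) -> AccumulationCurve:
    """Near-optimal accumulation by iterative maximum coverage.

    Each step adds the site contributing the most not-yet-represented
    species; ties go to the site with higher full-landscape RWR, then to
    the lexicographically smaller site id.  Once every species is covered,
    the remaining sites are appended by raw richness under the same
    tie-break.  The greedy guarantee bounds each prefix at (1 - 1/e) of
    the true optimum; on small instances :func:`exact_optimal_curve`
    verifies it is usually exact.
    """
    if occ.n_sites == 0:
        raise DataError("cannot build an optimal curve for an empty matrix")
    presence = occ.presence.astype(bool)
    n = occ.n_sites
    rwr = compute_rwr(occ, rarity_weights(occ)).as_array(list(map(str, occ.site_ids)))
    richness = occ.site_richness()
    site_names = np.array([str(s) for s in occ.site_ids], dtype=object)

    uncovered = presence.any(axis=0)
    remaining = np.ones(n, dtype=bool)
    order = np.empty(n, dtype=np.intp)
    for step in range(n):
        if uncovered.any():
            gains = presence[:, uncovered].sum(axis=1)
        else:
            gains = richness
        gains = np.where(remaining, gains, -1)
        best_gain = gains.max()
        tied = np.flatnonzero(gains == best_gain)
        if len(tied) > 1:
            # tolerance guards against summation-order jitter in RWR, which
            # would make tie-breaking depend on species column order
            tied = tied[rwr[tied] >= rwr[tied].max() - 1e-9]
            if len(tied) > 1:
                tied = tied[np.argsort(site_names[tied])][:1]
        pick = int(tied[0])
        order[step] = pick
        remaining[pick] = False
        uncovered &= ~presence[pick]
    return AccumulationCurve(
        ordered_sites=tuple(site_names[order]),
        S_k=_cumulative_species(occ, order),
        kind="optimal",
        n_sites=n,
        n_species=occ.n_species,
    )


def exact_optimal_curve(occ: OccurrenceMatrix, max_sites: int) -> AccumulationCurve:
    """True optimum O_k by exhaustive enumeration of all k-subsets.

    Feasible only up to 20 sites (2^N subset masks); this is the test
    oracle that certifies the greedy stand-in.  There is no single ordering
    achieving every O_k, so ``ordered_sites`` is empty.
    """
    n = occ.n_sites
    if n > 20:
        raise CapabilityError(
            f"exact optimum infeasible for {n} sites (limit 20); use greedy_optimal_curve"
        )
    if not 1 <= max_sites <= n:
        raise DataError(f"max_sites must be in 1..{n}, got {max_sites}")
    # species set of each site as a bitmask; DP over all subset masks
    site_bits = [
        int.from_bytes(np.packbits(occ.presence[i]).tobytes(), "big")
        for i in range(n)
    ]
    best = np.zeros(max_sites + 1, dtype=np.int64)
    union = np.zeros(1 << n, dtype=object)
    popcnt = np.zeros(1 << n, dtype=np.int64)
    for mask in range(1, 1 << n):
        low = mask & -mask
        site = low.bit_length() - 1
        union[mask] = union[mask ^ low] | site_bits[site]
        popcnt[mask] = popcnt[mask ^ low] + 1
        k = popcnt[mask]
        if k <= max_sites:
            count = int(union[mask]).bit_count()
            if count > best[k]:
                best[k] = count
    return AccumulationCurve(
        ordered_sites=(),
        S_k=best[1:].astype(float),
        kind="optimal",
        n_sites=n,
        n_species=occ.n_species,
    )


def expected_random_curve(occ: OccurrenceMatrix) -> AccumulationCurve:
    """Exact expected species count in k uniformly chosen sites, all k.

    For species j occupying c_j of N sites, the probability that a uniform
    k-subset misses it is C(N - c_j, k) / C(N, k); summing the complements
    over species gives R_k.  Evaluated in log space (gammaln) so large
    landscapes do not overflow; no Monte Carlo involved.
    """
    if occ.n_sites == 0:
        raise DataError("cannot build a random baseline for an empty matrix")
    n = occ.n_sites
    c = occ.occupancy_counts().astype(np.int64)
    c = c[c > 0]
    k = np.arange(1, n + 1)
    # log C(N - c_j, k) - log C(N, k), rows species, cols k; -inf when k > N - c_j
    def logc(m: np.ndarray, r: np.ndarray) -> np.ndarray:
        valid = r <= m
        out = np.where(
            valid, gammaln(m + 1) - gammaln(np.where(valid, r, 0) + 1)
            - gammaln(np.where(valid, m - r, 1) + 1), -np.inf
        )
        return out

    m = (n - c)[:, None].astype(float)
    kk = k[None, :].astype(float)
    log_miss = logc(m, kk) - logc(np.full_like(m, float(n)), kk)
    miss = np.exp(log_miss)
    R_k = (1.0 - miss).sum(axis=0)
    return AccumulationCurve(
        ordered_sites=(),
        S_k=R_k,
        kind="random_expected",
        n_sites=n,
        n_species=occ.n_species,
    )


def monte_carlo_random_curve(
    occ: OccurrenceMatrix, n_draws: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical mean and standard deviation of the random-draw curve.

    A cross-check for :func:`expected_random_curve`; returns (mean S_k,
    sd S_k) over ``n_draws`` uniform site orderings.
    """
    rng = np.random.default_rng(seed)
    n = occ.n_sites
    curves = np.empty((n_draws, n))
    for i in range(n_draws):
        curves[i] = _cumulative_species(occ, rng.permutation(n))
    return curves.mean(axis=0), curves.std(axis=0, ddof=1)


def fraction_steps(n_sites: int, fractions: Sequence[float]) -> list[int]:
    """Map top-fraction percentages to site counts k (round-half-up, >= 1)."""
    steps = []
    for f in fractions:
        if not 0 < f <= 100:
            raise DataError(f"fraction must be in (0, 100], got {f}")
        k = max(1, round_half_up(f * n_sites / 100.0))
        steps.append(min(k, n_sites))
    return sorted(set(steps))


def sai(
    surrogate: AccumulationCurve,
    optimal: AccumulationCurve,
    random: AccumulationCurve,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
) -> SaiValue:
    """Species Accumulation Index averaged over top landscape fractions.

    SAI_k = (S_k - R_k) / (O_k - R_k) at each step k given by the
    fractions; degenerate steps (optimal indistinguishable from random)
    are skipped; the result is the unweighted mean over the rest.
    """
    if not (surrogate.n_sites == optimal.n_sites == random.n_sites):
        raise ConsistencyError("curves computed on different landscapes (site counts differ)")
    if not (surrogate.n_species == optimal.n_species == random.n_species):
        raise ConsistencyError("curves computed on different landscapes (species counts differ)")
    steps = fraction_steps(surrogate.n_sites, fractions)
    sai_k: dict = {}
    for k in steps:
        if k > min(len(surrogate), len(optimal), len(random)):
            continue
        S, O, R = surrogate.at(k), optimal.at(k), random.at(k)
        if O - R < _EPS:
            continue
        sai_k[k] = (S - R) / (O - R)
    if not sai_k:
        raise EvaluationError("no evaluable steps: optimal never separates from random")
    return SaiValue(
        sai_k=sai_k,
        mean_sai=float(np.mean(list(sai_k.values()))),
        evaluated_steps=tuple(sorted(sai_k)),
    )
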