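"""Rarity-weighted richness (RWR).

Each species gets a rarity weight equal to the inverse of its occupancy,
w_i = 1 / c_i, where c_i is the number of sites the species occupies in the
matrix at hand.  A site's RWR is the sum of the weights of the species
present there:

    RWR(site) = sum over species present of 1 / c_i

Species occurring in a single site contribute a full point; widespread
species contribute little.  Summed over all sites, each species contributes
c_i * (1/c_i) = 1, so total RWR equals the number of occupied species — a
conservation identity the tests exploit.

Occupancy is always counted *within the matrix passed in*: when scoring a
q% inventoried subset for model training, c_i reflects only the subset,
because that is all the data a planner in that scenario has.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .core_data import OccurrenceMatrix
from .errors import ConsistencyError, DataError

__all__ = ["RarityWeights", "SiteScores", "rarity_weights", "compute_rwr"]


def matrix_hash(occ: OccurrenceMatrix) -> str:
    """Short content hash of an occurrence matrix, for provenance checks."""
    h = hashlib.sha256()
    h.update("\x1f".join(map(str, occ.site_ids)).encode())
    h.update(b"\x1e")
    h.update("\x1f".join(map(str, occ.species_ids)).encode())
    h.update(b"\x1e")
    h.update(np.ascontiguousarray(occ.presence).tobytes())
    return h.hexdigest()[:16]


@dataclass(frozen=True)
class RarityWeights:
    """Per-species weights 1/c_i, defined only for occupied species."""

    weights: Mapping[str, float]
    source_hash: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", dict(self.weights))
        for sp, w in self.weights.items():
            if not 0 < w <= 1:
                raise DataError(f"rarity weight for {sp!r} outside (0, 1]: {w}")

    def __getitem__(self, species: str) -> float:
        return self.weights[species]

    def __contains__(self, species: str) -> bool:
        return species in self.weights

    def __len__(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class SiteScores:
    """One real score per site: computed RWR or model-predicted PRWR.

    The ``label`` records which; ``source_hash`` ties RWR scores back to the
    matrix they were computed from.
    """

    scores: Mapping[str, float]
    label: Literal["RWR", "PRWR"]
    source_hash: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", dict(self.scores))
        vals = np.array(list(self.scores.values()), dtype=float)
        if vals.size and not np.isfinite(vals).all():
            raise DataError("site scores must be finite")
        if self.label not in ("RWR", "PRWR"):
            raise DataError(f"unknown score label: {self.label!r}")

    def __getitem__(self, site: str) -> float:
        return self.scores[site]

    def __len__(self) -> int:
        return len(self.scores)

    @property
    def site_ids(self) -> list[str]:
        return sorted(self.scores)

    def as_array(self, site_order) -> np.ndarray:
        """Scores aligned to ``site_order``."""
        try:
            return np.array([self.scores[s] for s in site_order], dtype=float)
        except KeyError as exc:
            raise ConsistencyError(f"site {exc.args[0]!r} has no score") from exc

    def to_csv(self, path: str | Path) -> None:
        """Write ``site_id,score`` with a comment line recording provenance."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# label={self.label} source={self.source_hash}\n")
            pd.DataFrame(
                {"site_id": self.site_ids,
                 "score": [self.scores[s] for s in self.site_ids]}
            ).to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SiteScores":
        with open(path, encoding="utf-8") as fh:
            first = fh.readline().strip()
            label, source = "RWR", ""
            if first.startswith("#"):
                fields = dict(tok.split("=", 1) for tok in first[1:].split())
                label = fields.get("label", "RWR")
                source = fields.get("source", "")
                df = pd.read_csv(fh, dtype={"site_id": str})
            else:
                fh.seek(0)
                df = pd.read_csv(fh, dtype={"site_id": str})
        return cls(dict(zip(df["site_id"], df["score"].astype(float))),
                   label=label, source_hash=source)  # type: ignore[arg-type]


def rarity_weights(occ: OccurrenceMatrix) -> RarityWeights:
    """Compute 1/c_i from the occupancy counts of ``occ``.

    Species with zero presences (possible in a subset view) are omitted:
    a planner's data contain no evidence they exist.
    """
    if occ.n_sites == 0 or occ.n_species == 0:
        raise DataError("cannot compute rarity weights on an empty matrix")
    counts = occ.occupancy_counts()
    occupied = counts > 0
    return RarityWeights(
        weights={
            str(sp): 1.0 / c
            for sp, c in zip(occ.species_ids[occupied], counts[occupied])
        },
        source_hash=matrix_hash(occ),
    )


def compute_rwr(occ: OccurrenceMatrix, w: RarityWeights) -> SiteScores:
    """Sum rarity weights over the species present at each site.

    ``w`` must have been derived from ``occ`` itself — scoring one matrix
    with weights from another silently changes the metric, so the pairing
    is enforced via the provenance hash.
    """
    src = matrix_hash(occ)
    if w.source_hash != src:
        raise ConsistencyError(
            "rarity weights were not derived from this occurrence matrix"
        )
    counts = occ.occupancy_counts()
    occupied = counts > 0
    missing = [str(sp) for sp in occ.species_ids[occupied] if str(sp) not in w]
    if missing:
        raise ConsistencyError(f"species present but unweighted: {missing[:5]}")
    wvec = np.zeros(occ.n_species)
    for j, sp in enumerate(occ.species_ids):
        if str(sp) in w:
            wvec[j] = w[str(sp)]
    scores = occ.presence.astype(float) @ wvec
    return SiteScores(
        scores=dict(zip(map(str, occ.site_ids), scores)),
        label="RWR",
        source_hash=src,
    )
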