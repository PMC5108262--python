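"""Domain containers and I/O for site-by-species and site-by-environment data.

The two central containers are :class:`OccurrenceMatrix` (binary sites x
species incidence — the single source of truth for occupancy counts and
species representation) and :class:`EnvironmentTable` (numeric covariates
per site).  Both keep identifiers in deterministic lexicographic order so
no result depends on file row order.

CSV layouts
-----------
long occurrence CSV
    header ``site_id,species_id``; one record per row; duplicates collapse
    silently to a single presence (atlas data are record lists).
wide occurrence CSV
    header ``site_id,<species>...``; cells strictly 0/1.
environment CSV
    header ``site_id,<variable>...``; decimal numbers, no missing values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigError, DataError, FormatError

__all__ = [
    "OccurrenceMatrix",
    "EnvironmentTable",
    "SiteSplit",
    "load_occurrences",
    "load_environment",
    "align",
    "sample_split",
    "round_half_up",
]


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(np.unique(ids)) != len(ids):
        dupes = pd.Series(ids).value_counts()
        dupes = list(dupes[dupes > 1].index[:5])
        raise DataError(f"duplicate {what} identifiers: {dupes}")


@dataclass(frozen=True)
class OccurrenceMatrix:
    """Binary sites x species incidence matrix.

    ``presence[i, j] == 1`` iff species ``species_ids[j]`` was recorded at
    site ``site_ids[i]``.  Column sums are the occupancy counts ``c_i``
    that drive every rarity computation.  A full-landscape matrix has no
    all-zero species column; a subset view (the q% inventoried sample) may.
    """

    site_ids: np.ndarray
    species_ids: np.ndarray
    presence: np.ndarray

    def __post_init__(self) -> None:
        site_ids = np.asarray(self.site_ids, dtype=object)
        species_ids = np.asarray(self.species_ids, dtype=object)
        presence = np.asarray(self.presence)
        if presence.shape != (len(site_ids), len(species_ids)):
            raise DataError(
                f"presence shape {presence.shape} does not match "
                f"{len(site_ids)} sites x {len(species_ids)} species"
            )
        if presence.size and not np.isin(presence, (0, 1)).all():
            raise DataError("presence entries must be 0 or 1")
        _check_unique(site_ids, "site")
        _check_unique(species_ids, "species")
        object.__setattr__(self, "site_ids", site_ids)
        object.__setattr__(self, "species_ids", species_ids)
        object.__setattr__(self, "presence", presence.astype(np.int8))

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def occupancy_counts(self) -> np.ndarray:
        """Per-species occupancy c_i (column sums), aligned to species_ids."""
        return self.presence.sum(axis=0).astype(np.int64)

    def site_richness(self) -> np.ndarray:
        """Per-site species counts (row sums)."""
        return self.presence.sum(axis=1).astype(np.int64)

    def subset_sites(self, sites: Iterable[str]) -> "OccurrenceMatrix":
        """Row-subset view restricted to ``sites``, in lexicographic order.

        Species columns are retained even when empty in the subset: the
        rarity layer decides how to treat zero-occupancy species.
        """
        wanted = sorted(set(sites))
        index = {s: i for i, s in enumerate(self.site_ids)}
        missing = [s for s in wanted if s not in index]
        if missing:
            raise DataError(f"sites not in matrix: {missing[:5]}")
        rows = np.array([index[s] for s in wanted], dtype=np.intp)
        return OccurrenceMatrix(
            site_ids=np.array(wanted, dtype=object),
            species_ids=self.species_ids,
            presence=self.presence[rows],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.presence, index=pd.Index(self.site_ids, name="site_id"),
            columns=list(self.species_ids),
        )

    def to_wide_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    def to_long_csv(self, path: str | Path) -> None:
        rows, cols = np.nonzero(self.presence)
        pd.DataFrame(
            {"site_id": self.site_ids[rows], "species_id": self.species_ids[cols]}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class EnvironmentTable:
    """Numeric site covariates; the predictor pool for PCA selection and
    the RWR model.  Missing values are a hard error — the intended inputs
    are complete raster summaries, and silent imputation would leak into
    every downstream prediction."""

    site_ids: np.ndarray
    variable_names: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        site_ids = np.asarray(self.site_ids, dtype=object)
        names = np.asarray(self.variable_names, dtype=object)
        values = np.asarray(self.values, dtype=np.float64)
        if values.shape != (len(site_ids), len(names)):
            raise DataError(
                f"values shape {values.shape} does not match "
                f"{len(site_ids)} sites x {len(names)} variables"
            )
        if values.size and not np.isfinite(values).all():
            bad = [str(n) for n in names[np.where(~np.isfinite(values))[1][:5]]]
            raise DataError(f"missing/non-finite environment values in: {bad}")
        _check_unique(site_ids, "site")
        _check_unique(names, "variable")
        object.__setattr__(self, "site_ids", site_ids)
        object.__setattr__(self, "variable_names", names)
        object.__setattr__(self, "values", values)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_variables(self) -> int:
        return len(self.variable_names)

    def subset_sites(self, sites: Iterable[str]) -> "EnvironmentTable":
        wanted = sorted(set(sites))
        index = {s: i for i, s in enumerate(self.site_ids)}
        missing = [s for s in wanted if s not in index]
        if missing:
            raise DataError(f"sites not in environment table: {missing[:5]}")
        rows = np.array([index[s] for s in wanted], dtype=np.intp)
        return EnvironmentTable(
            site_ids=np.array(wanted, dtype=object),
            variable_names=self.variable_names,
            values=self.values[rows],
        )

    def columns(self, names: Iterable[str]) -> np.ndarray:
        """Value matrix restricted to ``names`` (in the given order)."""
        index = {n: i for i, n in enumerate(self.variable_names)}
        missing = [n for n in names if n not in index]
        if missing:
            raise DataError(f"variables not in table: {missing}")
        return self.values[:, [index[n] for n in names]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.site_ids, name="site_id"),
            columns=list(self.variable_names),
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


@dataclass(frozen=True)
class SiteSplit:
    """A q% inventoried / (100-q)% holdout partition of the landscape.

    The inventoried set mimics the sites a planner has species data for;
    the holdout's biological data are set aside entirely.
    """

    inventoried: frozenset = field()
    holdout: frozenset = field()
    q: float = field()
    seed: int = field()

    def __post_init__(self) -> None:
        object.__setattr__(self, "inventoried", frozenset(self.inventoried))
        object.__setattr__(self, "holdout", frozenset(self.holdout))
        if self.inventoried & self.holdout:
            raise DataError("inventoried and holdout sets overlap")


def round_half_up(x: float) -> int:
    """Deterministic, symmetric rounding (0.5 always rounds up).

    Used for subset sizes so ``q * N / 100`` never depends on banker's
    rounding quirks.
    """
    return int(np.floor(x + 0.5))


def load_occurrences(path: str | Path, format: Literal["long", "wide"]) -> OccurrenceMatrix:
    """Load an occurrence matrix from a long or wide CSV.

    Duplicate (site, species) records collapse to a single presence.
    Identifiers are sorted lexicographically regardless of file order.
    """
    path = Path(path)
    if format == "long":
        try:
            df = pd.read_csv(path, dtype=str)
        except pd.errors.EmptyDataError as exc:
            raise DataError(f"empty occurrence file: {path}") from exc
        for col in ("site_id", "species_id"):
            if col not in df.columns:
                raise FormatError(f"long occurrence CSV must have a '{col}' column")
        if df.empty:
            raise DataError(f"occurrence file has no records: {path}")
        df = df.drop_duplicates()
        sites = np.array(sorted(df["site_id"].unique()), dtype=object)
        species = np.array(sorted(df["species_id"].unique()), dtype=object)
        si = {s: i for i, s in enumerate(sites)}
        pj = {p: j for j, p in enumerate(species)}
        presence = np.zeros((len(sites), len(species)), dtype=np.int8)
        presence[
            df["site_id"].map(si).to_numpy(), df["species_id"].map(pj).to_numpy()
        ] = 1
        return OccurrenceMatrix(sites, species, presence)
    if format == "wide":
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError as exc:
            raise DataError(f"empty occurrence file: {path}") from exc
        if "site_id" not in df.columns:
            raise FormatError("wide occurrence CSV must have a 'site_id' column")
        if df.empty or df.shape[1] < 2:
            raise DataError(f"occurrence file has no species columns or rows: {path}")
        df = df.set_index(df["site_id"].astype(str)).drop(columns="site_id")
        mat = df.to_numpy()
        if not np.isin(mat, (0, 1)).all():
            raise FormatError("wide occurrence CSV cells must be 0 or 1")
        df = df.sort_index()
        df = df[sorted(df.columns)]
        return OccurrenceMatrix(
            np.array(df.index, dtype=object),
            np.array(df.columns, dtype=object),
            df.to_numpy(dtype=np.int8),
        )
    raise ConfigError(f"unknown occurrence format: {format!r} (use 'long' or 'wide')")


def load_environment(path: str | Path) -> EnvironmentTable:
    """Load a site-by-variable environment CSV (header ``site_id,<var>...``)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"empty environment file: {path}") from exc
    if "site_id" not in df.columns:
        raise FormatError("environment CSV must have a 'site_id' column")
    if df.empty or df.shape[1] < 2:
        raise DataError(f"environment file has no variables or rows: {path}")
    df = df.set_index(df["site_id"].astype(str)).drop(columns="site_id").sort_index()
    df = df[sorted(df.columns)]
    try:
        values = df.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise FormatError(f"non-numeric environment values: {exc}") from exc
    return EnvironmentTable(
        np.array(df.index, dtype=object), np.array(df.columns, dtype=object), values
    )


def align(occ: OccurrenceMatrix, env: EnvironmentTable) -> tuple[OccurrenceMatrix, EnvironmentTable]:
    """Restrict both tables to their common sites in identical order.

    Every occurrence site must have an environment row; environment-only
    sites are allowed (covariates are typically available landscape-wide).
    """
    env_sites = set(env.site_ids)
    missing = [s for s in occ.site_ids if s not in env_sites]
    if missing:
        raise AlignmentError(
            f"{len(missing)} occurrence sites lack environment rows, e.g. {missing[:5]}"
        )
    common = sorted(set(occ.site_ids))
    return occ.subset_sites(common), env.subset_sites(common)


def sample_split(occ: OccurrenceMatrix, q: float, seed: int) -> SiteSplit:
    """Simple random sample (without replacement) of round(qN/100) sites.

    The inventoried sites stand in for the q% of the landscape the planner
    has inventories for; the rest are holdout.  Reproducible under ``seed``.
    """
    if not 0 < q <= 100:
        raise ConfigError(f"q must be in (0, 100], got {q}")
    n = occ.n_sites
    if n < 5:
        raise ConfigError(f"need at least 5 sites to split, got {n}")
    size = round_half_up(q * n / 100.0)
    if size < 2:
        raise ConfigError(
            f"q={q}% of {n} sites gives a subset of {size} < 2; increase q"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n, size=size, replace=False)
    inventoried = frozenset(occ.site_ids[chosen])
    holdout = frozenset(occ.site_ids) - inventoried
    return SiteSplit(inventoried=inventoried, holdout=holdout, q=q, seed=seed)
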