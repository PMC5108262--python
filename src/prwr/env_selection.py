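"""Environmental-variable reduction by PCA.

Climate/remote-sensing predictor pools are strongly collinear, so before
modelling, the pool is reduced to one representative variable per major
environmental gradient: run PCA on the correlation matrix of the
standardized variables, retain components with eigenvalue > 1 (Kaiser
rule), and for each retained component pick the variable most correlated
(|Pearson r|) with its scores.

Correlation-matrix (not covariance) PCA is used throughout: the variables
mix units (degrees, millimetres, unitless indices) and the Kaiser rule
presupposes unit-variance inputs.  A consequence the tests rely on is that
rescaling any variable by a positive constant changes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import EnvironmentTable
from .errors import DataError, PreprocessingError

__all__ = ["PcaResult", "PredictorSet", "pca_factors", "select_predictors"]


@dataclass(frozen=True)
class PcaResult:
    """Correlation-matrix PCA of an environment table.

    ``eigenvalues`` are descending and sum to the number of variables;
    ``n_retained`` counts those strictly above 1, with a floor of one
    component so degenerate pools still yield a predictor.
    """

    eigenvalues: np.ndarray
    component_scores: np.ndarray  # site x component
    loadings: np.ndarray  # variable x component
    variable_names: np.ndarray
    n_retained: int


@dataclass(frozen=True)
class PredictorSet:
    """One representative variable per retained component.

    ``provenance`` records, per selected variable, the component it
    represents and the |correlation| that won it the slot.
    """

    selected: tuple
    provenance: tuple  # of (component_index, abs_correlation)

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise DataError("duplicate variables in predictor set")

    def __len__(self) -> int:
        return len(self.selected)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "component": [c for c, _ in self.provenance],
                "variable": list(self.selected),
                "abs_correlation": [r for _, r in self.provenance],
            }
        ).to_csv(path, index=False)


def pca_factors(env: EnvironmentTable) -> PcaResult:
    """PCA of the standardized variables, Kaiser retention (eigenvalue > 1).

    The comparison is strict ``> 1`` with no tolerance.  If no eigenvalue
    exceeds 1 (possible only for near-spherical pools), the top component
    is retained so downstream selection never returns an empty set.
    """
    if env.n_variables < 2:
        raise PreprocessingError("PCA needs at least 2 variables")
    sd = env.values.std(axis=0, ddof=1)
    dead = sd <= 0
    if dead.any():
        names = [str(n) for n in env.variable_names[dead]]
        raise PreprocessingError(f"zero-variance variables: {names}")
    z = (env.values - env.values.mean(axis=0)) / sd
    corr = np.corrcoef(env.values, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # deterministic sign: largest-|entry| loading positive per component
    for k in range(eigvecs.shape[1]):
        pivot = np.argmax(np.abs(eigvecs[:, k]))
        if eigvecs[pivot, k] < 0:
            eigvecs[:, k] = -eigvecs[:, k]
    scores = z @ eigvecs
    n_retained = max(1, int((eigvals > 1.0).sum()))
    return PcaResult(
        eigenvalues=eigvals,
        component_scores=scores,
        loadings=eigvecs * np.sqrt(eigvals),
        variable_names=env.variable_names,
        n_retained=n_retained,
    )


def select_predictors(env: EnvironmentTable, pca: PcaResult) -> PredictorSet:
    """Pick, per retained component, the variable most correlated with it.

    A variable may top the correlation ranking of two components; it is
    kept for the component where its |r| is larger and the runner-up fills
    the other slot.  Implemented as a greedy assignment over all
    (variable, component) pairs in descending |r| order, with ties broken
    by variable name then component index, so the outcome is deterministic.
    """
    if not np.array_equal(pca.variable_names, env.variable_names):
        raise DataError("PCA was not computed from this environment table")
    k = pca.n_retained
    sd = env.values.std(axis=0, ddof=1)
    z = (env.values - env.values.mean(axis=0)) / sd
    comp = pca.component_scores[:, :k]
    comp_sd = comp.std(axis=0, ddof=1)
    comp_sd[comp_sd == 0] = 1.0
    zc = (comp - comp.mean(axis=0)) / comp_sd
    absr = np.abs(z.T @ zc) / (env.n_sites - 1)  # variables x components

    pairs = sorted(
        ((float(absr[v, c]), str(env.variable_names[v]), c)
         for v in range(env.n_variables) for c in range(k)),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    chosen: dict[int, tuple[str, float]] = {}
    used: set[str] = set()
    for r, name, c in pairs:
        if c in chosen or name in used:
            continue
        chosen[c] = (name, r)
        used.add(name)
        if len(chosen) == k:
            break
    if len(chosen) < k:
        raise DataError(
            f"only {len(chosen)} variables available for {k} retained components"
        )
    selected = tuple(chosen[c][0] for c in range(k))
    provenance = tuple((c, chosen[c][1]) for c in range(k))
    return PredictorSet(selected=selected, provenance=provenance)
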