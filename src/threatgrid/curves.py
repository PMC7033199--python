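"""Partial-dependence-style response curves from blocked-fold ensembles.

For each covariate, predictions are made to a profile data set in which
every other covariate is held at its mean (mode for categorical
covariates) while the focal covariate sweeps the central 90% of its
observed range; the mean and SD of the predictions across the fold
models give the curve and its uncertainty band.  Paired curves contrast
the response of threatened richness (modelled with total richness as a
covariate) with that of total richness (modelled without it).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .forest import EnsembleResult, fit_cv_ensemble

__all__ = ["ResponseCurve", "partial_dependence", "paired_curves"]


@dataclass
class ResponseCurve:
    """Mean ± SD predicted response along one covariate's central range."""

    variable: str
    grid: np.ndarray  # strictly ascending, 5th..95th percentile
    mean: np.ndarray
    sd: np.ndarray
    response: str
    scope: str = "global"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.variable,
                "response": self.response,
                "grid_value": self.grid,
                "mean": self.mean,
                "sd": self.sd,
            }
        )


def _percentile_grid(x: np.ndarray, n_points: int, central: float) -> np.ndarray:
    lo_q = (1.0 - central) / 2.0
    lo, hi = np.quantile(x, [lo_q, 1.0 - lo_q])
    if hi <= lo:
        raise ValueError("focal variable has (near-)zero variance over the grid")
    return np.linspace(lo, hi, n_points)


def partial_dependence(
    ensemble: EnsembleResult,
    data: pd.DataFrame,
    variable: str,
    n_points: int = 50,
    categorical: Sequence[str] = (),
    central: float = 0.90,
    full_data: bool = False,
) -> ResponseCurve:
    """Response of the ensemble to one covariate, others at reference values.

    Default semantics follow the held-at-mean profile construction: a
    single synthetic row with every non-focal covariate at its mean
    (mode for covariates listed in ``categorical``, ties to the smallest
    value) and the focal covariate swept over ``n_points`` equally
    spaced values between its 5th and 95th percentiles.  With
    ``full_data=True`` the classical partial dependence is computed
    instead (predictions averaged over the observed rows at each grid
    value).
    """
    if variable not in ensemble.covariate_names:
        raise ValueError(f"{variable!r} not among the ensemble covariates")
    names = ensemble.covariate_names
    grid = _percentile_grid(data[variable].to_numpy(dtype=float), n_points, central)

    if full_data:
        base = data[names].to_numpy(dtype=float).copy()
        col = names.index(variable)
        per_model = np.empty((len(ensemble.models), n_points))
        for gi, val in enumerate(grid):
            base[:, col] = val
            for mi, model in enumerate(ensemble.models):
                per_model[mi, gi] = model.predict(base).mean()
    else:
        profile = np.empty(len(names))
        for i, name in enumerate(names):
            x = data[name]
            if name in categorical:
                counts = x.value_counts()
                top = counts.max()
                profile[i] = min(v for v, c in counts.items() if c == top)
            else:
                profile[i] = float(x.mean())
        X = np.tile(profile, (n_points, 1))
        X[:, names.index(variable)] = grid
        per_model = np.vstack([model.predict(X) for model in ensemble.models])

    return ResponseCurve(
        variable=variable,
        grid=grid,
        mean=per_model.mean(axis=0),
        sd=per_model.std(axis=0, ddof=0),
        response=ensemble.response,
        scope=ensemble.scope,
    )


def paired_curves(
    data: pd.DataFrame,
    folds,
    variables: Sequence[str],
    covariate_names: Sequence[str],
    m: int = 3,
    nt: int = 1000,
    seed: int = 0,
    n_points: int = 50,
    categorical: Sequence[str] = (),
) -> tuple[dict[str, tuple[ResponseCurve, ResponseCurve]], EnsembleResult, EnsembleResult]:
    """Curves for threatened and total richness from separately fitted models.

    The threatened-richness ensemble uses ``covariate_names`` plus total
    richness as a predictor; the total-richness ensemble uses the same
    set barring total richness.  Curves for the two responses share the
    evaluation grid per variable.  Returns ``(curves, threatened
    ensemble, total ensemble)`` with ``curves[var] = (threatened_curve,
    total_curve)``.
    """
    covariate_names = [c for c in covariate_names if c != "total_richness"]
    threat_covs = covariate_names + ["total_richness"]
    rng = np.random.default_rng(seed)
    ens_threat = fit_cv_ensemble(
        data,
        folds,
        m=m,
        nt=nt,
        response="threatened_richness",
        covariate_names=threat_covs,
        seed=int(rng.integers(0, 2**31 - 1)),
        scope="global threatened",
    )
    ens_total = fit_cv_ensemble(
        data,
        folds,
        m=m,
        nt=nt,
        response="total_richness",
        covariate_names=covariate_names,
        seed=int(rng.integers(0, 2**31 - 1)),
        scope="global total",
    )
    curves: dict[str, tuple[ResponseCurve, ResponseCurve]] = {}
    for var in variables:
        c_thr = partial_dependence(
            ens_threat, data, var, n_points=n_points, categorical=categorical
        )
        c_tot = partial_dependence(
            ens_total, data, var, n_points=n_points, categorical=categorical
        )
        c_tot.grid = c_thr.grid  # shared grid (identical by construction)
        curves[var] = (c_thr, c_tot)
    return curves, ens_threat, ens_total
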