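"""Randomization variable importance and category-level comparison.

Importance of a covariate in a fitted model is measured by permuting the
covariate's observed column (predictions made to the full data set),
recomputing the mean squared prediction error, and taking

    VI = sqrt((MSE_rand - MSE_obs) / MSE_obs)

averaged over many random permutations.  The square root puts the
statistic on the scale of a relative prediction-error increase; a
covariate the model never uses leaves the MSE unchanged and scores 0.
Covariates are grouped into categories — total species richness (S),
environmental (E) and human impact (H) — and the category means are
compared across the blocked-fold models with a repeated-measures ANOVA
and pairwise post-hoc contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import pingouin as pg
from scipy.stats import norm

__all__ = [
    "ImportanceRecord",
    "CategoryComparison",
    "vi_from_mse",
    "variable_importance",
    "importance_table",
    "summarize_importance",
    "compare_categories",
]


def vi_from_mse(mse_rand: float, mse_obs: float) -> float:
    """Single-repeat importance: sqrt((MSE_rand - MSE_obs) / MSE_obs).

    Clamped to 0 when randomisation happens to reduce the error (the
    radicand is then negative, which the statistic leaves undefined).
    """
    if mse_obs <= 0:
        raise ValueError("MSE_obs must be positive; VI undefined")
    ratio = (mse_rand - mse_obs) / mse_obs
    return float(np.sqrt(ratio)) if ratio > 0 else 0.0


@dataclass(frozen=True)
class ImportanceRecord:
    """Mean randomization importance of one variable in one model."""

    model_index: int
    variable: str
    vi_mean: float
    vi_sd: float
    n_repeats: int
    n_clamped: int  # repeats with MSE_rand < MSE_obs, clamped to VI = 0
    category: str | None = None


def _mse(y: np.ndarray, pred: np.ndarray) -> float:
    return float(np.mean((y - pred) ** 2))


def variable_importance(
    model,
    data: pd.DataFrame,
    response: str,
    variable: str,
    covariate_names: list[str],
    n_repeats: int = 1000,
    seed: int = 0,
    model_index: int = 0,
) -> ImportanceRecord:
    """Randomization importance of one covariate in one fitted model.

    Randomisation is a uniform permutation of the observed column over
    all cells (the marginal distribution is preserved).  Repeats where
    permutation happens to *reduce* the MSE have a negative radicand;
    such repeats are clamped to VI = 0 and counted in ``n_clamped``.
    """
    if variable not in covariate_names:
        raise ValueError(f"{variable!r} is not a covariate of this model")
    X = data[covariate_names].to_numpy(dtype=float)
    y = data[response].to_numpy(dtype=float)
    mse_obs = _mse(y, model.predict(X))
    if mse_obs == 0:
        raise ValueError("MSE_obs is zero (perfect model); VI undefined")
    col = covariate_names.index(variable)
    rng = np.random.default_rng(seed)
    n = len(X)
    vi = np.empty(n_repeats)
    n_clamped = 0
    # batch permuted copies into one predict call per chunk: tree
    # traversal dominates, but per-call overhead is worth amortising
    chunk = max(1, min(n_repeats, 100))
    done = 0
    while done < n_repeats:
        b = min(chunk, n_repeats - done)
        Xp = np.tile(X, (b, 1))
        for r in range(b):
            Xp[r * n : (r + 1) * n, col] = X[rng.permutation(n), col]
        preds = model.predict(Xp).reshape(b, n)
        mse_rand = ((y[None, :] - preds) ** 2).mean(axis=1)
        ratio = (mse_rand - mse_obs) / mse_obs
        neg = ratio < 0
        n_clamped += int(neg.sum())
        vi[done : done + b] = np.where(neg, 0.0, np.sqrt(np.clip(ratio, 0.0, None)))
        done += b
    return ImportanceRecord(
        model_index=model_index,
        variable=variable,
        vi_mean=float(vi.mean()),
        vi_sd=float(vi.std(ddof=1)) if n_repeats > 1 else 0.0,
        n_repeats=n_repeats,
        n_clamped=n_clamped,
    )


def importance_table(
    ensemble,
    data: pd.DataFrame,
    categories: Mapping[str, str] | None = None,
    n_repeats: int = 1000,
    seed: int = 0,
    retained: list[int] | None = None,
) -> pd.DataFrame:
    """VI of every covariate in every retained fold model.

    ``retained`` lists fold-model indices to keep (models failing an
    R^2 floor are excluded upstream); default keeps all.  Returns a long
    table (model, variable, category, vi_mean, vi_sd, n_repeats,
    n_clamped).
    """
    if retained is None:
        retained = list(range(len(ensemble.models)))
    if not retained:
        raise ValueError("no retained models; importance undefined")
    categories = dict(categories or {})
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(
        len(retained) * len(ensemble.covariate_names)
    )]
    rows = []
    i = 0
    for mi in retained:
        model = ensemble.models[mi]
        for var in ensemble.covariate_names:
            rec = variable_importance(
                model,
                data,
                ensemble.response,
                var,
                ensemble.covariate_names,
                n_repeats=n_repeats,
                seed=seeds[i],
                model_index=mi,
            )
            i += 1
            rows.append(
                {
                    "model": mi,
                    "variable": var,
                    "category": categories.get(
                        var, "S" if var == "total_richness" else None
                    ),
                    "vi_mean": rec.vi_mean,
                    "vi_sd": rec.vi_sd,
                    "n_repeats": rec.n_repeats,
                    "n_clamped": rec.n_clamped,
                }
            )
    return pd.DataFrame(rows)


def summarize_importance(records: pd.DataFrame) -> pd.DataFrame:
    """Per-variable median and IQR of VI across models, ranked by median."""
    g = records.groupby("variable")["vi_mean"]
    out = pd.DataFrame(
        {
            "median_vi": g.median(),
            "q1_vi": g.quantile(0.25),
            "q3_vi": g.quantile(0.75),
            "mean_vi": g.mean(),
        }
    )
    cat = records.groupby("variable")["category"].first()
    out["category"] = cat
    out = out.sort_values("median_vi", ascending=False)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


@dataclass
class CategoryComparison:
    """Repeated-measures comparison of category-mean importances."""

    contrasts: pd.DataFrame  # contrast, estimate, se, z, p, p_adj
    f_statistic: float
    df1: float
    df2: float
    p_value: float
    category_means: pd.DataFrame  # model x category mean VI


_CONTRASTS = (("E", "H"), ("S", "H"), ("S", "E"))


def compare_categories(records: pd.DataFrame) -> CategoryComparison:
    """Compare mean importance of the S, E and H categories across models.

    Per model, VI is averaged over the variables within each category
    (S is the single total-richness variable); the three category means
    are compared with a repeated-measures ANOVA (model as the subject
    factor) and pairwise post-hoc contrasts E-H, S-H, S-E.  Contrasts
    are paired-difference normal-approximation z tests with single-step
    Šidák multiplicity adjustment.
    """
    need = {"S", "E", "H"}
    present = set(records["category"].dropna().unique())
    if not need <= present:
        raise ValueError(f"categories missing from records: {sorted(need - present)}")
    models = records["model"].unique()
    if len(models) < 2:
        raise ValueError("need at least two models for a repeated-measures ANOVA")

    means = (
        records[records["category"].isin(need)]
        .groupby(["model", "category"])["vi_mean"]
        .mean()
        .unstack("category")
    )

    long = means.reset_index().melt(
        id_vars="model", var_name="category", value_name="mean_vi"
    )
    try:
        aov = pg.rm_anova(
            data=long, dv="mean_vi", within="category", subject="model",
            detailed=True,
        )
        aov = aov.rename(columns={"p-unc": "p_unc"})  # pingouin version drift
        row = aov.loc[aov["Source"] == "category"].iloc[0]
        f_stat = float(row["F"])
        p_unc = float(row["p_unc"])
        df1 = float(row["DF"])
        err = aov.loc[aov["Source"] != "category", "DF"]
        df2 = float(err.iloc[0]) if len(err) else float(
            (len(means) - 1) * (means.shape[1] - 1)
        )
    except (KeyError, ValueError, ZeroDivisionError):
        # zero-variance input: the F ratio is 0/0 and undefined
        f_stat = p_unc = float("nan")
        df1 = float(means.shape[1] - 1)
        df2 = float((len(means) - 1) * (means.shape[1] - 1))

    rows = []
    n = len(means)
    for a, b in _CONTRASTS:
        diff = means[a] - means[b]
        est = float(diff.mean())
        se = float(diff.std(ddof=1) / np.sqrt(n))
        if se == 0:
            z = 0.0 if est == 0 else np.inf * np.sign(est)
        else:
            z = est / se
        p = float(2.0 * norm.sf(abs(z))) if np.isfinite(z) else 0.0
        rows.append(
            {"contrast": f"{a}-{b}", "estimate": est, "se": se, "z": z, "p": p}
        )
    contrasts = pd.DataFrame(rows)
    # single-step Šidák family-wise adjustment over the three contrasts
    contrasts["p_adj"] = 1.0 - (1.0 - contrasts["p"]) ** len(contrasts)

    return CategoryComparison(
        contrasts=contrasts,
        f_statistic=f_stat,
        df1=df1,
        df2=df2,
        p_value=p_unc,
        category_means=means,
    )
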