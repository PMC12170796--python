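"""Statistical linkage between synchrony, condition and relational outcomes.

Pre/post ratings are standardized to the pre-exercise mean and SD (so a
post-exercise value of +1 reads "one pre-exercise SD above the pre-exercise
mean"); variables without a pre value are z-scored. Dyad-level change scores
(post minus pre, averaged over the two members) feed ordinary least-squares
models; rating-level analyses use linear mixed models with crossed random
intercepts for participant, dyad, partner and round. Real-vs-pseudo-pair
synchrony differences are tested with pooled-variance two-sample t-tests
under a Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .synthdata import MEASURES

__all__ = [
    "ModelFit",
    "standardize",
    "dyad_change_scores",
    "fit_ols",
    "fit_ols_formula",
    "fit_dyadic_mixed",
    "default_contrasts",
    "pair_vs_pseudo_tests",
    "hr_changes_from_signals",
    "hr_change_model",
]


@dataclass
class ModelFit:
    """Tidy fit summary: one row per fixed-effect term."""

    terms: list[str]
    estimates: np.ndarray
    se: np.ndarray
    stat: np.ndarray
    df: float
    pvalues: np.ndarray
    n: int
    descriptor: str = ""
    extra: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.estimates,
                "se": self.se,
                "stat": self.stat,
                "df": self.df,
                "p": self.pvalues,
                "n": self.n,
                "model": self.descriptor,
            }
        )

    def __getitem__(self, term: str) -> dict:
        i = self.terms.index(term)
        return {
            "estimate": float(self.estimates[i]),
            "se": float(self.se[i]),
            "stat": float(self.stat[i]),
            "p": float(self.pvalues[i]),
        }


# ---------------------------------------------------------------------------
# Standardization and change scores


def standardize(table: pd.DataFrame, variable: str, by_condition: bool = False) -> pd.DataFrame:
    """Scale one measure of a long ratings table.

    Measures with pre values: both pre and post are scaled by the
    *pre-exercise* mean and SD (pooled across conditions unless
    ``by_condition``). Post-only measures are z-scored by their own mean/SD.
    """
    out = table.copy()
    mask = out["measure"] == variable
    if not mask.any():
        raise ValueError(f"measure {variable!r} not present")

    def _scale(df_mask: pd.Series) -> None:
        pre = out.loc[df_mask, "pre"]
        if pre.notna().any():
            mu, sd = float(pre.mean()), float(pre.std(ddof=1))
            src = "pre"
        else:
            post = out.loc[df_mask, "post"]
            mu, sd = float(post.mean()), float(post.std(ddof=1))
            src = "post"
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"zero {src}-value SD for measure {variable!r}; cannot standardize")
        out.loc[df_mask, "pre"] = (out.loc[df_mask, "pre"] - mu) / sd
        out.loc[df_mask, "post"] = (out.loc[df_mask, "post"] - mu) / sd

    if by_condition:
        for cond in dict.fromkeys(out.loc[mask, "condition"]):
            _scale(mask & (out["condition"] == cond))
    else:
        _scale(mask)
    return out


def dyad_change_scores(ratings: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-dyad change scores: mean over members of (post - pre).

    Post-only measures contribute the mean post value instead (column
    ``mean_<measure>``). Dyads with a missing member (fewer than two raters)
    are excluded and listed in the second return value.
    """
    rows = []
    excluded = []
    for (dyad, cond, rnd, sess), g in ratings.groupby(
        ["dyad_id", "condition", "round", "session"], sort=True
    ):
        raters = sorted(set(g["rater"]))
        if len(raters) < 2:
            excluded.append({"dyad_id": dyad, "reason": f"only {len(raters)} rater(s)"})
            continue
        row = {"dyad_id": dyad, "condition": cond, "round": rnd, "session": sess}
        for measure, gm in g.groupby("measure"):
            has_pre = MEASURES.get(measure, (None,) * 6)[5] if measure in MEASURES else gm["pre"].notna().any()
            if has_pre:
                change = gm["post"] - gm["pre"]
                row[f"change_{measure}"] = float(change.mean()) if change.notna().all() else np.nan
            else:
                row[f"mean_{measure}"] = float(gm["post"].mean())
        rows.append(row)
    return pd.DataFrame(rows), pd.DataFrame(excluded, columns=["dyad_id", "reason"])


# ---------------------------------------------------------------------------
# OLS


def _collinear_terms(X: pd.DataFrame) -> list[str]:
    bad, kept = [], []
    for col in X.columns:
        trial = X[kept + [col]].to_numpy(dtype=float)
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(col)
        else:
            bad.append(col)
    return bad


def fit_ols(y, X: pd.DataFrame, descriptor: str = "ols") -> ModelFit:
    """Closed-form least squares with classical SEs and t p-values on n-k df.

    ``X`` must be a full-rank design matrix with named columns (include an
    intercept column explicitly if wanted). A perfect fit (zero residual
    variance) is flagged in ``extra['perfect_fit']``.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if np.linalg.matrix_rank(X.to_numpy(dtype=float)) < X.shape[1]:
        raise ValueError(f"rank-deficient design; collinear terms: {_collinear_terms(X)}")
    res = sm.OLS(y, X).fit()
    perfect = bool(res.ssr <= 1e-12 * max(1.0, float(np.sum(y**2))))
    return ModelFit(
        terms=list(X.columns),
        estimates=np.asarray(res.params),
        se=np.asarray(res.bse),
        stat=np.asarray(res.tvalues),
        df=float(res.df_resid),
        pvalues=np.asarray(res.pvalues),
        n=int(res.nobs),
        descriptor=descriptor,
        extra={"perfect_fit": perfect, "r_squared": float(res.rsquared)},
    )


def fit_ols_formula(data: pd.DataFrame, formula: str, descriptor: str | None = None) -> ModelFit:
    """Formula-interface OLS (dummy codings via ``C(cond, Treatment('ref'))``)."""
    model = smf.ols(formula, data=data)
    X = pd.DataFrame(model.exog, columns=model.exog_names)
    return fit_ols(model.endog, X, descriptor=descriptor or formula)


# ---------------------------------------------------------------------------
# Dyadic mixed models


def fit_dyadic_mixed(
    data: pd.DataFrame,
    formula: str,
    random_factors=("participant", "dyad", "partner", "round"),
    reml: bool = True,
    prune_tol: float = 1e-6,
    descriptor: str | None = None,
) -> ModelFit:
    """Linear mixed model with crossed random intercepts for dyadic data.

    Random intercepts are fitted as variance components over a single
    grouping (the whole sample), which accommodates the crossed structure of
    speed-dating designs (a participant appears in several dyads, a dyad
    involves two participants). When the fit fails to converge or a
    component's variance collapses toward zero, the worst-performing random
    intercept is dropped and the model refitted; the pruning path is recorded
    in ``extra['dropped']``. With every component pruned the model
    degenerates to OLS.
    """
    factors = [f for f in random_factors if f in data.columns]
    for f in random_factors:
        if f not in data.columns:
            raise ValueError(f"random factor {f!r} not a column of data")
    factors = [f for f in factors if data[f].nunique() >= 2]
    dropped: list[str] = []
    df = data.copy()
    df["_all"] = 1

    while factors:
        vcf = {f: f"0 + C({f})" for f in factors}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(formula, df, groups="_all", vc_formula=vcf, re_formula="0")
                res = model.fit(reml=reml)
            vcomp = np.asarray(res.vcomp, dtype=float)
            converged = bool(getattr(res, "converged", True)) and np.all(np.isfinite(vcomp))
        except (np.linalg.LinAlgError, ValueError):
            converged, vcomp, res = False, None, None

        if converged:
            scale = float(res.scale) if np.isfinite(res.scale) and res.scale > 0 else 1.0
            rel = vcomp / scale
            if np.all(rel > prune_tol):
                k = len(res.fe_params)
                return ModelFit(
                    terms=list(res.fe_params.index),
                    estimates=np.asarray(res.fe_params),
                    se=np.asarray(res.bse_fe),
                    stat=np.asarray(res.tvalues[:k]),
                    df=np.inf,  # Wald z inference
                    pvalues=np.asarray(res.pvalues[:k]),
                    n=int(res.nobs),
                    descriptor=descriptor or f"mixed: {formula} | {'+'.join(factors)}",
                    extra={
                        "variance_components": dict(zip(factors, vcomp)),
                        "residual_variance": float(res.scale),
                        "dropped": dropped,
                        "reml": reml,
                    },
                )
            worst = factors[int(np.argmin(rel))]
        else:
            worst = factors[-1]
        dropped.append(worst)
        factors = [f for f in factors if f != worst]

    ols = smf.ols(formula, df).fit()
    return ModelFit(
        terms=list(ols.params.index),
        estimates=np.asarray(ols.params),
        se=np.asarray(ols.bse),
        stat=np.asarray(ols.tvalues),
        df=float(ols.df_resid),
        pvalues=np.asarray(ols.pvalues),
        n=int(ols.nobs),
        descriptor=descriptor or f"ols (all random intercepts pruned): {formula}",
        extra={"variance_components": {}, "dropped": dropped},
    )


# ---------------------------------------------------------------------------
# Pair-vs-pseudo tests


def default_contrasts(conditions: list[str]) -> list[dict]:
    """The six canonical contrasts: real vs pseudo within each condition and
    real-pair differences between each pair of conditions."""
    contrasts = [
        {
            "label": f"{c}: pairs vs pseudo",
            "a": {"condition": c, "pair_type": "real"},
            "b": {"condition": c, "pair_type": "pseudo"},
        }
        for c in conditions
    ]
    for i, c1 in enumerate(conditions):
        for c2 in conditions[i + 1 :]:
            contrasts.append(
                {
                    "label": f"pairs: {c1} vs {c2}",
                    "a": {"condition": c1, "pair_type": "real"},
                    "b": {"condition": c2, "pair_type": "real"},
                }
            )
    return contrasts


def _select(table: pd.DataFrame, sel: dict, value_col: str) -> np.ndarray:
    mask = np.ones(len(table), dtype=bool)
    for col, val in sel.items():
        mask &= (table[col] == val).to_numpy()
    vals = table.loc[mask, value_col].to_numpy(dtype=float)
    return vals[np.isfinite(vals)]


def pair_vs_pseudo_tests(
    table: pd.DataFrame,
    comparisons: list[dict] | None = None,
    alpha: float = 0.05,
    value_col: str = "r",
    welch: bool = False,
) -> pd.DataFrame:
    """Independent two-sample t-tests with Bonferroni correction.

    Default contrasts are the six canonical ones built from the conditions in
    the table. Pooled-variance (Student) t is the default, giving
    df = n1 + n2 - 2; Welch is available by flag. The per-test threshold is
    alpha / m for m comparisons.
    """
    if comparisons is None:
        conditions = [c for c in dict.fromkeys(table["condition"])]
        comparisons = default_contrasts(conditions)
    m = len(comparisons)
    if m == 0:
        raise ValueError("no comparisons supplied")
    threshold = alpha / m
    rows = []
    for comp in comparisons:
        a = _select(table, comp["a"], value_col)
        b = _select(table, comp["b"], value_col)
        if a.size < 2 or b.size < 2:
            raise ValueError(f"contrast {comp['label']!r} has an arm with fewer than 2 observations")
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        df = a.size + b.size - 2 if not welch else np.nan
        rows.append(
            {
                "contrast": comp["label"],
                "n_a": a.size,
                "n_b": b.size,
                "mean_a": float(np.mean(a)),
                "mean_b": float(np.mean(b)),
                "t": float(t),
                "df": df,
                "p": float(p),
                "alpha": alpha,
                "m": m,
                "threshold": threshold,
                "significant": bool(p < threshold),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# HR change


def hr_changes_from_signals(signals: dict) -> pd.DataFrame:
    """Final-minus-first HR (bpm) per participant x round, from raw series."""
    rows = []
    for (participant, rnd, modality), s in signals.items():
        if modality != "hr" or s.n_samples < 2:
            continue
        rows.append(
            {
                "participant": participant,
                "round": rnd,
                "condition": s.condition,
                "change": float(s.values[-1] - s.values[0]),
            }
        )
    return pd.DataFrame(rows)


def hr_change_model(changes: pd.DataFrame) -> dict[str, ModelFit]:
    """Per condition: intercept-only model of HR change (final minus first).

    With repeated participation, a participant random intercept is included;
    with each participant contributing a single change score the model is the
    one-sample t-test on the changes. A residual-free fit (all changes
    identical) is flagged in ``extra['degenerate']``.
    """
    out: dict[str, ModelFit] = {}
    for cond, g in changes.groupby("condition", sort=False):
        y = g["change"].to_numpy(dtype=float)
        if y.size < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 change scores")
        repeats = g["participant"].duplicated().any()
        degenerate = float(np.std(y, ddof=1)) == 0.0
        if repeats and not degenerate:
            fit = fit_dyadic_mixed(
                g.rename(columns={"change": "y"}),
                "y ~ 1",
                random_factors=("participant",),
                descriptor=f"hr change ~ 1 + (1|participant), condition {cond}",
            )
        else:
            X = pd.DataFrame({"Intercept": np.ones(y.size)})
            fit = fit_ols(y, X, descriptor=f"hr change ~ 1, condition {cond}")
        fit.extra["degenerate"] = degenerate
        out[str(cond)] = fit
    return out
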