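"""Per-feature covariate-adjusted age association.

Each protein (log2 relative abundance) or splicing event (PSI) is
regressed on donor age with a linear mixed model adjusting for sex, race,
physical-activity category, BMI and — for proteins — the slow/fast
myosin fiber ratio, with the multiplexing batch as a random intercept.
The age coefficient beta is the mean change of the response per year of
age; p-values come from Satterthwaite t-tests and are Benjamini-Hochberg
adjusted across the tested feature set.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .lmm import LMMDesign, RandomInterceptFit

__all__ = [
    "categorize_activity",
    "compute_fiber_ratio",
    "build_design",
    "fit_feature_lmm",
    "satterthwaite_pvalue",
    "bh_adjust",
    "classify_age_assoc",
    "associate_features",
    "presence_mask",
]

SLOW_MYOSIN = "MYH7"
FAST_MYOSINS = ("MYH1", "MYH2", "MYH4")

#: fixed effects used for protein models; splicing models drop fiber_ratio
PROTEIN_COVARIATES = ("age", "sex", "race", "activity_category", "bmi", "fiber_ratio")
RNA_COVARIATES = ("age", "sex", "race", "activity_category", "bmi")


def categorize_activity(minutes):
    """Ordinal physical-activity category from weekly moderate-to-vigorous minutes.

    0 = not active (<30 min/week); 1 = moderately active [30, 75);
    2 = active [75, 150); 3 = highly active (>=150).
    """
    arr = np.asarray(minutes, dtype=float)
    if np.any(arr < 0):
        raise ValueError("activity minutes must be non-negative")
    cat = np.select([arr < 30, arr < 75, arr < 150], [0, 1, 2], default=3)
    if np.isscalar(minutes) or arr.ndim == 0:
        return int(cat)
    return cat.astype(int)


def compute_fiber_ratio(matrix: pd.DataFrame) -> pd.Series:
    """Slow/fast fiber-type proxy per donor: MYH7 / (MYH1 + MYH2 + MYH4).

    The ratio is taken on the linear intensity scale (the matrix holds
    log2 relative abundance, so values are exponentiated first). A fast
    isoform missing for a donor contributes 0 provided at least one fast
    isoform is observed; donors with MYH7 missing, all fast isoforms
    missing, or a zero denominator get a missing ratio.
    """
    if SLOW_MYOSIN not in matrix.index:
        raise KeyError(f"{SLOW_MYOSIN} not quantified; cannot form fiber ratio")
    fast_present = [m for m in FAST_MYOSINS if m in matrix.index]
    if not fast_present:
        raise KeyError("no fast-twitch myosin (MYH1/MYH2/MYH4) quantified")
    slow = np.exp2(matrix.loc[SLOW_MYOSIN].astype(float))
    fast_lin = np.exp2(matrix.loc[fast_present].astype(float))
    any_fast = fast_lin.notna().any(axis=0)
    denom = fast_lin.sum(axis=0, min_count=1).where(any_fast)
    ratio = slow / denom
    ratio[denom <= 0] = np.nan
    ratio.name = "fiber_ratio"
    return ratio


def build_design(
    covariates: pd.DataFrame,
    fiber_ratio: pd.Series | None = None,
    include_fiber: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Fixed-effect design matrix from the donor covariate table.

    Age, BMI and the ordinal activity category enter numerically; sex and
    race as reference-coded dummies. Returns (design, names) indexed by
    donor; rank deficiency raises naming the collinear columns.
    """
    cols = {"intercept": np.ones(len(covariates)), "age": covariates["age"].astype(float)}
    sex_d = pd.get_dummies(covariates["sex"].astype(str), prefix="sex", drop_first=True)
    race_d = pd.get_dummies(covariates["race"].astype(str), prefix="race", drop_first=True)
    X = pd.DataFrame(cols, index=covariates.index)
    X = pd.concat([X, sex_d.astype(float), race_d.astype(float)], axis=1)
    X["activity_category"] = covariates["activity_category"].astype(float)
    X["bmi"] = covariates["bmi"].astype(float)
    if include_fiber:
        if fiber_ratio is None:
            raise ValueError("include_fiber=True requires a fiber_ratio series")
        X["fiber_ratio"] = fiber_ratio.reindex(covariates.index).astype(float)
    names = list(X.columns)
    complete = X.dropna()
    if np.linalg.matrix_rank(complete.to_numpy()) < len(names):
        from .lmm import _suspect_columns

        raise np.linalg.LinAlgError(
            "singular design; collinear columns among: "
            + ", ".join(_suspect_columns(complete.to_numpy(), names))
        )
    return X, names


def fit_feature_lmm(
    y: pd.Series,
    design: pd.DataFrame,
    groups: pd.Series,
) -> RandomInterceptFit:
    """REML fit of one feature: drops donors with missing response or
    covariates (listwise), then fits the random-intercept model."""
    df = design.copy()
    df["_y"] = y.reindex(design.index)
    df["_g"] = groups.reindex(design.index)
    df = df.dropna()
    X = df.drop(columns=["_y", "_g"])
    return LMMDesign(X.to_numpy(), list(X.columns), df["_g"].to_numpy()).fit(
        df["_y"].to_numpy()
    )


def satterthwaite_pvalue(fit: RandomInterceptFit, coefficient: str = "age"):
    """(df, p) for one fixed effect via the Satterthwaite approximation."""
    return fit.satterthwaite(coefficient)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (same order as input)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def presence_mask(
    matrix: pd.DataFrame,
    donors: pd.DataFrame,
    rule: str = "per_stratum",
    min_per_stratum: int = 3,
) -> pd.Series:
    """Per-feature presence gate used in the age-associated call.

    ``per_stratum``: observed in >= min_per_stratum donors of every age
    stratum. ``half_or_per_stratum``: that, or observed in >= 50% of all
    donors.
    """
    observed = matrix.notna()
    strata = donors.loc[matrix.columns, "stratum"]
    per_stratum = observed.T.groupby(strata, observed=True).sum().T
    ok_stratum = (per_stratum >= min_per_stratum).all(axis=1)
    if rule == "per_stratum":
        return ok_stratum
    if rule == "half_or_per_stratum":
        half = observed.sum(axis=1) >= 0.5 * matrix.shape[1]
        return ok_stratum | half
    raise ValueError(f"unknown presence rule: {rule}")


def classify_age_assoc(
    results: pd.DataFrame,
    alpha: float = 0.05,
    presence: pd.Series | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Label each feature over/under/none and summarize the counts.

    ``over``: beta_age > 0, p < alpha and the presence gate holds;
    ``under``: the same with beta_age < 0; everything else ``none``.
    """
    res = results.copy()
    ok = res["p"] < alpha
    if presence is not None:
        ok &= presence.reindex(res.index).fillna(False).astype(bool)
    res["direction"] = np.where(
        ok & (res["beta_age"] > 0), "over", np.where(ok & (res["beta_age"] < 0), "under", "none")
    )
    n_assoc = int((res["direction"] != "none").sum())
    counts = {
        "n_tested": int(len(res)),
        "n_age_associated": n_assoc,
        "n_over": int((res["direction"] == "over").sum()),
        "n_under": int((res["direction"] == "under").sum()),
        "pct_age_associated": 100.0 * n_assoc / max(len(res), 1),
    }
    counts["pct_over_of_assoc"] = 100.0 * counts["n_over"] / max(n_assoc, 1)
    counts["pct_under_of_assoc"] = 100.0 * counts["n_under"] / max(n_assoc, 1)
    return res, counts


def associate_features(
    matrix: pd.DataFrame,
    donors: pd.DataFrame,
    include_fiber: bool = True,
    random_col: str = "tmt_batch",
    alpha: float = 0.05,
    presence_rule: str = "per_stratum",
    min_obs: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Fit the age model for every row of a feature x donor matrix.

    Returns a results table (feature, n_obs, beta_age, se, df, p, q,
    direction) and the summary counts. Features with too few
    observations, fewer than two batches, or a rank-deficient subset
    design are reported with missing statistics and excluded from the
    BH family.
    """
    donors = donors.loc[matrix.columns]
    fiber = compute_fiber_ratio(matrix) if include_fiber else None
    design, names = build_design(donors, fiber, include_fiber=include_fiber)
    groups = donors[random_col]
    min_obs = min_obs if min_obs is not None else len(names) + 2

    # cache LMM designs by donor-availability pattern: most features share one
    cache: dict[bytes, LMMDesign] = {}
    Xfull = design.to_numpy(dtype=float)
    gfull = groups.to_numpy()
    cov_ok = ~np.isnan(Xfull).any(axis=1)

    rows = []
    for feat, y in matrix.iterrows():
        yv = y.to_numpy(dtype=float)
        mask = cov_ok & np.isfinite(yv)
        n_obs = int(mask.sum())
        rec = {"feature": feat, "n_obs": n_obs, "beta_age": np.nan, "se": np.nan,
               "df": np.nan, "p": np.nan}
        if n_obs >= min_obs and len(np.unique(gfull[mask])) >= 2 and np.nanstd(yv[mask]) > 0:
            key = mask.tobytes()
            try:
                dsg = cache.get(key)
                if dsg is None:
                    dsg = LMMDesign(Xfull[mask], names, gfull[mask])
                    cache[key] = dsg
                fit = dsg.fit(yv[mask])
                j = "age"
                df_s, p = fit.satterthwaite(j)
                rec.update(
                    beta_age=fit.coef(j), se=float(fit.bse[names.index(j)]),
                    df=df_s, p=p,
                )
            except np.linalg.LinAlgError as exc:  # rank-deficient subset
                warnings.warn(f"{feat}: {exc}")
        rows.append(rec)
    res = pd.DataFrame(rows).set_index("feature")
    tested = res["p"].notna()
    res["q"] = np.nan
    if tested.any():
        res.loc[tested, "q"] = bh_adjust(res.loc[tested, "p"].to_numpy())
    pres = presence_mask(matrix, donors, rule=presence_rule)
    res, summary = classify_age_assoc(res, alpha=alpha, presence=pres)
    return res, summary
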