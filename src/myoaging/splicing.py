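"""PSI quantification and age-associated splicing models.

Percent spliced-in (PSI) of a local event in a donor is the TPM of the
event's inclusion transcripts divided by the TPM of all transcripts
participating in the event. Per-event age models reuse the protein
mixed-model engine with the same donor covariates minus the fiber
ratio, and the RNA-seq experiment batch as the random intercept.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .association import associate_features, build_design, fit_feature_lmm
from .events import ASEvent, EVENT_TYPES

__all__ = [
    "compute_psi_matrix",
    "filter_expressed_transcripts",
    "fit_event_age_model",
    "fit_psi_matrix",
    "psi_age_trend",
    "event_class_background",
    "write_ioe",
]

#: total event TPM below this floor gives an undefined (missing) PSI
PSI_TPM_FLOOR = 1e-3


def compute_psi_matrix(
    events: list[ASEvent],
    tpm: pd.DataFrame,
    floor: float = PSI_TPM_FLOOR,
) -> pd.DataFrame:
    """Event x donor PSI from a transcript x donor TPM table.

    ``PSI = sum TPM(inclusion) / sum TPM(total)``; denominators below
    ``floor`` give a missing entry. Events referencing transcripts not
    present in the table raise.
    """
    rows = []
    index = []
    for ev in events:
        missing = ev.total_transcripts - set(tpm.index)
        if missing:
            raise KeyError(
                f"{ev.event_id}: transcripts absent from TPM table: {sorted(missing)}"
            )
        inc = tpm.loc[sorted(ev.inclusion_transcripts)].sum(axis=0)
        tot = tpm.loc[sorted(ev.total_transcripts)].sum(axis=0)
        psi = inc / tot
        psi[tot < floor] = np.nan
        rows.append(psi)
        index.append(ev.event_id)
    out = pd.DataFrame(rows, index=pd.Index(index, name="event_id"))
    return out


def filter_expressed_transcripts(
    tpm: pd.DataFrame,
    donors: pd.DataFrame,
    min_per_group: int = 3,
) -> tuple[pd.DataFrame, float]:
    """Keep transcripts expressed (TPM > 0) in at least ``min_per_group``
    donors of every age stratum; returns the excluded fraction."""
    strata = donors.loc[tpm.columns, "stratum"]
    expressed = tpm.gt(0)
    per_group = expressed.T.groupby(strata, observed=True).sum().T
    keep = (per_group >= min_per_group).all(axis=1)
    excluded_fraction = float((~keep).mean()) if len(keep) else 0.0
    return tpm.loc[keep], excluded_fraction


def fit_event_age_model(
    psi_row: pd.Series,
    donors: pd.DataFrame,
    random_col: str = "rna_batch",
    min_obs: int = 10,
) -> dict:
    """Mixed-model age fit for one event's PSI row.

    Fixed effects: age, sex, race, activity category, BMI (no fiber
    ratio); random intercept: RNA batch. Constant rows and rows with
    fewer than ``min_obs`` finite values are flagged as skipped.
    """
    y = psi_row.astype(float)
    finite = y.dropna()
    if len(finite) < min_obs:
        return {"skipped": "too_few_observations", "n_obs": int(len(finite))}
    if float(finite.std()) == 0.0:
        return {"skipped": "constant_psi", "n_obs": int(len(finite))}
    design, names = build_design(donors.loc[y.index], include_fiber=False)
    fit = fit_feature_lmm(y, design, donors.loc[y.index, random_col])
    df, p = fit.satterthwaite("age")
    return {
        "beta_age": fit.coef("age"),
        "se": float(fit.bse[names.index("age")]),
        "df": df,
        "p": p,
        "n_obs": fit.n,
        "skipped": None,
    }


def fit_psi_matrix(
    psi: pd.DataFrame,
    donors: pd.DataFrame,
    alpha: float = 0.05,
    random_col: str = "rna_batch",
    presence_rule: str = "per_stratum",
    min_obs: int = 10,
) -> tuple[pd.DataFrame, dict]:
    """Age models for every event row of a PSI matrix.

    Returns the per-event results (beta in PSI units per year, p, BH q,
    direction) and summary counts; significant events with positive
    beta are the "positive" (more included with age) set.
    """
    res, summary = associate_features(
        psi,
        donors,
        include_fiber=False,
        random_col=random_col,
        alpha=alpha,
        presence_rule=presence_rule,
        min_obs=min_obs,
    )
    res = res.copy()
    res["sign"] = res["direction"].map(
        {"over": "positive", "under": "negative", "none": "none"}
    )
    summary["n_positive"] = summary.pop("n_over")
    summary["n_negative"] = summary.pop("n_under")
    summary["n_significant_events"] = summary.pop("n_age_associated")
    return res, summary


def psi_age_trend(psi: pd.DataFrame, donors: pd.DataFrame) -> dict:
    """Cohort-level splicing trend: each donor's mean PSI over the given
    (typically age-associated) events, regressed on age by OLS.

    Returns slope (PSI/year), r2, p and the per-donor means.
    """
    if psi.shape[1] < 2:
        raise ValueError("need at least two donors")
    mean_psi = psi.mean(axis=0, skipna=True)
    ages = donors.loc[mean_psi.index, "age"].astype(float)
    if float(mean_psi.std()) < 1e-14:  # degenerate: no between-donor variation
        return {"slope": 0.0, "r2": 0.0, "p": 1.0, "mean_psi": mean_psi}
    fit = stats.linregress(ages, mean_psi)
    return {
        "slope": float(fit.slope),
        "r2": float(fit.rvalue**2),
        "p": float(fit.pvalue),
        "mean_psi": mean_psi,
    }


def event_class_background(
    events: list[ASEvent] | pd.Series,
    annotation_events: list[ASEvent] | pd.Series,
) -> pd.DataFrame:
    """Proportion of each of the 7 event classes in an observed set (e.g.
    the age-associated events) versus a background set (all events
    derivable from the annotation), with per-class differences."""

    def proportions(evs):
        types = pd.Series(
            [e.event_type if isinstance(e, ASEvent) else str(e) for e in evs]
        )
        counts = types.value_counts().reindex(EVENT_TYPES, fill_value=0)
        total = counts.sum()
        return counts / total if total else counts.astype(float)

    obs = proportions(events)
    bg = proportions(annotation_events)
    return pd.DataFrame(
        {"observed": obs, "background": bg, "difference": obs - bg},
        index=pd.Index(EVENT_TYPES, name="event_type"),
    )


def write_ioe(events: list[ASEvent]) -> str:
    """Serialize events in the SUPPA ``.ioe`` tab format."""
    lines = ["seqname\tgene_id\tevent_id\tinclusion_transcripts\ttotal_transcripts"]
    for ev in events:
        lines.append(
            "\t".join(
                [
                    ev.chrom,
                    ev.gene_id,
                    ev.event_id,
                    ",".join(sorted(ev.inclusion_transcripts)),
                    ",".join(sorted(ev.total_transcripts)),
                ]
            )
        )
    return "\n".join(lines) + "\n"
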