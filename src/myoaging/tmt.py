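"""Reporter-ion processing: from per-batch spectrum tables to one
cross-batch, normalized log2 protein x donor abundance matrix.

The pipeline order is: QC filtering -> predictive-mean-matching
imputation of sparse missing channels -> log2 transform with per-protein
median centering (within batch) -> peptide-to-protein roll-up by median
-> sample-loading correction (channel medians polished to zero) ->
internal-reference bridging across batches (log-space subtraction of the
pooled reference channel) -> stratum-coverage filtering.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import CHANNEL_COLUMNS, REFERENCE_CHANNEL

__all__ = [
    "filter_spectra",
    "impute_reporters",
    "normalize_within_protein",
    "rollup_proteins",
    "correct_loading",
    "bridge_batches",
    "filter_by_stratum_coverage",
    "process_batches",
]

_CH = list(CHANNEL_COLUMNS)


def filter_spectra(spectra: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove decoy, contaminant and shared spectra, and spectra with more
    than two missing reporter channels.

    Returns the retained table and removal counts per reason (a spectrum
    is counted once, at the first reason that applies).
    """
    df = spectra
    counts = {"decoy": 0, "contaminant": 0, "shared": 0, "too_many_missing": 0}
    keep = pd.Series(True, index=df.index)
    for reason in ("decoy", "contaminant", "shared"):
        hit = df[reason].astype(bool) & keep
        counts[reason] = int(hit.sum())
        keep &= ~hit
    n_missing = df[_CH].isna().sum(axis=1)
    hit = (n_missing > 2) & keep
    counts["too_many_missing"] = int(hit.sum())
    keep &= ~hit
    return df[keep].copy(), counts


def impute_reporters(
    spectra: pd.DataFrame,
    max_iter: int = 10,
    seed: int = 0,
    k: int = 5,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Chained-equation imputation of missing reporter intensities by
    predictive mean matching (PMM), per batch.

    Channels are imputed round-robin: each incomplete channel is
    regressed (in log2 space) on the other five over the batch's
    spectrum x channel table, and every missing cell receives the
    observed intensity of one of the ``k`` spectra with the nearest
    predicted mean, drawn at random. Iterations stop at ``max_iter`` or
    when imputed values stabilize. Imputed values are therefore always
    members of the observed value set of their channel. A single
    imputation is retained.
    """
    if (spectra[_CH].isna().sum(axis=1) > 2).any():
        raise ValueError("spectra with more than two missing channels must be filtered first")
    rng = np.random.default_rng(seed)
    out = spectra.copy()
    for batch, idx in out.groupby("batch").groups.items():
        raw = out.loc[idx, _CH].to_numpy(dtype=float)
        miss = np.isnan(raw)
        if not miss.any():
            continue
        if miss.all(axis=0).any():
            ch = _CH[int(np.where(miss.all(axis=0))[0][0])]
            raise ValueError(f"batch {batch}: channel {ch} has no observed values")
        log = np.log2(raw, where=~miss, out=np.full_like(raw, np.nan))
        filled = log.copy()
        col_med = np.nanmedian(log, axis=0)
        for c in range(6):
            filled[miss[:, c], c] = col_med[c]
        raw_filled = raw.copy()
        for it in range(max_iter):
            delta = 0.0
            for c in range(6):
                m = miss[:, c]
                if not m.any():
                    continue
                X = np.column_stack([np.ones(len(filled)), np.delete(filled, c, axis=1)])
                coef, *_ = np.linalg.lstsq(X[~m], log[~m, c], rcond=None)
                pred = X @ coef
                obs_idx = np.where(~m)[0]
                order = np.argsort(pred[obs_idx])
                sorted_pred = pred[obs_idx][order]
                for row in np.where(m)[0]:
                    pos = np.searchsorted(sorted_pred, pred[row])
                    lo = max(0, pos - k)
                    hi = min(len(obs_idx), pos + k)
                    window = obs_idx[order[lo:hi]]
                    dist = np.abs(pred[window] - pred[row])
                    donors_k = window[np.argsort(dist)[:k]]
                    donor = rng.choice(donors_k)
                    new = log[donor, c]
                    delta = max(delta, abs(filled[row, c] - new))
                    filled[row, c] = new
                    raw_filled[row, c] = raw[donor, c]
            if delta < tol:
                break
        out.loc[idx, _CH] = raw_filled
    return out


def normalize_within_protein(spectra: pd.DataFrame) -> pd.DataFrame:
    """Log2 transform and per-protein median centering.

    For each protein within a batch, the median over all of its spectra
    and channels is subtracted, so each protein's pooled median is zero.
    Non-positive intensities raise, naming the spectrum.
    """
    vals = spectra[_CH].to_numpy(dtype=float)
    bad = ~(vals > 0) | ~np.isfinite(vals)
    if bad.any():
        row = int(np.where(bad.any(axis=1))[0][0])
        raise ValueError(
            f"non-positive or missing intensity in spectrum "
            f"{spectra['spectrum_id'].iloc[row]}"
        )
    out = spectra.copy()
    log = np.log2(vals)
    out[_CH] = log
    med = (
        out.melt(id_vars=["batch", "protein"], value_vars=_CH, value_name="v")
        .groupby(["batch", "protein"], observed=True)["v"]
        .median()
    )
    center = pd.MultiIndex.from_frame(out[["batch", "protein"]]).map(med).to_numpy()
    out[_CH] = log - center[:, None]
    return out


def rollup_proteins(spectra: pd.DataFrame) -> dict[object, pd.DataFrame]:
    """Per-batch protein x channel matrices: the median over a protein's
    spectra per channel. Proteins with a single spectrum pass through."""
    return {
        batch: sub.groupby("protein", observed=True)[_CH].median()
        for batch, sub in spectra.groupby("batch", observed=True)
    }


def correct_loading(matrix: pd.DataFrame) -> pd.DataFrame:
    """Sample-loading (median polish) correction of one batch matrix:
    subtract each channel's median so all channel medians are zero."""
    empty = matrix[_CH].notna().sum(axis=0).eq(0)
    if empty.any():
        raise ValueError(
            "channel(s) without observed entries: "
            + ", ".join(c for c, e in zip(_CH, empty) if e)
        )
    return matrix[_CH] - matrix[_CH].median(axis=0)


def bridge_batches(
    batch_matrices: dict[object, pd.DataFrame],
    donors: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Internal-reference bridging: per protein and batch, subtract the
    reference-channel value from the donor channels, then concatenate the
    donor columns of all batches.

    Proteins absent from a batch are missing for that batch's donors;
    proteins missing in a batch's reference channel cannot be bridged
    there and are set missing (counted).
    """
    ref_col = CHANNEL_COLUMNS[REFERENCE_CHANNEL - 1]
    counts = {"missing_reference": 0}
    pieces = []
    for batch, mat in batch_matrices.items():
        sub = donors[donors["tmt_batch"] == batch]
        if sub.empty:
            raise ValueError(f"no donors assigned to batch {batch}")
        ref = mat[ref_col]
        counts["missing_reference"] += int(ref.isna().sum())
        cols = {}
        for donor_id, ch in zip(sub.index, sub["tmt_channel"]):
            cols[donor_id] = mat[CHANNEL_COLUMNS[ch - 1]] - ref
        pieces.append(pd.DataFrame(cols))
    matrix = pd.concat(pieces, axis=1)
    matrix = matrix[donors.index[donors.index.isin(matrix.columns)]]
    matrix.index.name = "protein"
    return matrix, counts


def filter_by_stratum_coverage(
    matrix: pd.DataFrame,
    donors: pd.DataFrame,
    min_per_stratum: int = 3,
    rule: str = "per_stratum",
) -> tuple[pd.DataFrame, list, list]:
    """Keep proteins quantified in enough donors of every age stratum.

    ``per_stratum`` requires >= ``min_per_stratum`` observed donors in
    each of the five strata; ``half_or_per_stratum`` additionally admits
    proteins observed in at least half of all donors. Returns (filtered
    matrix, retained ids, excluded ids).
    """
    if matrix.empty:
        import warnings

        warnings.warn("empty protein matrix; nothing to filter")
        return matrix, [], []
    from .association import presence_mask

    keep = presence_mask(matrix, donors, rule=rule, min_per_stratum=min_per_stratum)
    retained = list(matrix.index[keep])
    excluded = list(matrix.index[~keep])
    return matrix.loc[keep], retained, excluded


def process_batches(
    spectra: pd.DataFrame,
    donors: pd.DataFrame,
    seed: int = 0,
    coverage_rule: str = "per_stratum",
    min_per_stratum: int = 3,
    max_iter: int = 10,
) -> tuple[pd.DataFrame, dict]:
    """Full reporter-ion pipeline; returns the bridged, coverage-filtered
    protein x donor matrix and a QC report of per-stage counts."""
    qc: dict = {"n_spectra_in": int(len(spectra))}
    kept, removed = filter_spectra(spectra)
    qc["removed"] = removed
    qc["n_spectra_kept"] = int(len(kept))
    complete = impute_reporters(kept, max_iter=max_iter, seed=seed)
    qc["n_imputed_cells"] = int(kept[_CH].isna().to_numpy().sum())
    centered = normalize_within_protein(complete)
    mats = rollup_proteins(centered)
    mats = {b: correct_loading(m) for b, m in mats.items()}
    qc["channel_medians_post"] = {
        str(b): [float(x) for x in m.median(axis=0)] for b, m in mats.items()
    }
    matrix, bridge_counts = bridge_batches(mats, donors)
    qc.update(bridge_counts)
    filtered, retained, excluded = filter_by_stratum_coverage(
        matrix, donors, min_per_stratum=min_per_stratum, rule=coverage_rule
    )
    qc["n_proteins_retained"] = len(retained)
    qc["n_proteins_excluded"] = len(excluded)
    return filtered, qc
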