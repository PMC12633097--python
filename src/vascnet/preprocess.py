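"""Normalisation, missingness filtering, log2 transform, PCA outlier flags.

Order of operations in the pipeline: zeros -> missing and per-sample sum
scaling (every sample's present-intensity total brought to the cohort
maximum), protein filtering on missing fraction, log2 transform, then PCA
screening of sample outliers.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .datatypes import AbundanceMatrix

log = logging.getLogger(__name__)


def sum_scale(raw: AbundanceMatrix) -> AbundanceMatrix:
    """Scale each sample so its present-intensity sum equals the maximum
    sample sum; cells equal to 0 become missing first (zero intensity means
    not quantified, not absent)."""
    raw.require_tag("raw")
    vals = raw.values.where(raw.values != 0.0)
    totals = vals.sum(axis=0, skipna=True)
    if (totals == 0).any() or totals.isna().any():
        bad = totals.index[(totals == 0) | totals.isna()]
        raise ValueError(f"samples with zero present-intensity sum: {list(bad)[:5]}")
    scaled = vals * (totals.max() / totals)
    return raw.with_values(scaled, scale_tag="sum_scaled")


def filter_missing(X: AbundanceMatrix, max_missing_frac: float = 0.5
                   ) -> AbundanceMatrix:
    """Retain proteins whose missing fraction is strictly below
    ``max_missing_frac`` (a protein missing in exactly half the samples is
    removed at the 0.5 default). Order preserved."""
    if not (0.0 < max_missing_frac <= 1.0):
        raise ValueError("max_missing_frac must lie in (0, 1]")
    frac = X.values.isna().mean(axis=1)
    keep = frac < max_missing_frac
    removed = int((~keep).sum())
    log.info("filter_missing: removed %d of %d proteins (threshold %.3g)",
             removed, X.n_proteins, max_missing_frac)
    out = X.subset_proteins(X.protein_ids[keep])
    return out


def log2_transform(X: AbundanceMatrix) -> AbundanceMatrix:
    """Elementwise log2 of sum-scaled intensities; missing preserved."""
    X.require_tag("sum_scaled")
    vals = X.values.to_numpy()
    if np.any(vals[np.isfinite(vals)] <= 0):
        raise ValueError("nonpositive present value; cannot log2 transform")
    return X.with_values(np.log2(X.values), scale_tag="log2")


def pca_outlier_flag(X: AbundanceMatrix, n_components: int = 2,
                     sd_threshold: float = 4.0) -> list[str]:
    """Flag samples whose score on any of the first ``n_components``
    principal components exceeds ``sd_threshold`` standard deviations of that
    component's scores (strict >).

    Missing values are imputed with the per-protein mean for the
    decomposition only; the matrix is untouched and removal is a separate,
    explicit step by the caller.
    """
    if X.n_samples < 3:
        raise ValueError("need at least 3 samples for PCA outlier detection")
    vals = X.values.to_numpy(dtype=float)
    row_mean = np.nanmean(vals, axis=1, keepdims=True)
    filled = np.where(np.isnan(vals), row_mean, vals)
    n_components = min(n_components, X.n_samples - 1, X.n_proteins)
    scores = PCA(n_components=n_components, svd_solver="full"
                 ).fit_transform(filled.T)
    sd = scores.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf
    flagged = np.abs(scores) > sd_threshold * sd
    return [s for s, f in zip(X.sample_ids, flagged.any(axis=1)) if f]
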