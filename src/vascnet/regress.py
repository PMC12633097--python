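"""Covariate cleanup by nonparametric bootstrap regression, plus per-factor
variance-explained diagnostics.

For every protein an OLS model of log2 abundance on the nuisance covariates
(cell proportion, age, PMI, batch, ...) is fitted on bootstrap resamples of
samples; the median bootstrap coefficient of each nuisance covariate is
subtracted (times the centered covariate) from the matrix.  Protected terms
(e.g. diagnosis) may be included in the fit but are never subtracted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import AbundanceMatrix, SampleManifest

log = logging.getLogger(__name__)

#: manifest columns treated as categorical in design matrices
CATEGORICAL = {"batch", "sex", "group"}


@dataclass
class RegressionSpec:
    covariates_to_remove: list[str] = field(
        default_factory=lambda: ["cell_proportion", "age", "pmi", "batch"])
    protected: list[str] = field(default_factory=list)
    n_bootstrap: int = 1000
    seed: int = 0

    def validate(self) -> None:
        overlap = set(self.covariates_to_remove) & set(self.protected)
        if overlap:
            raise ValueError(f"covariates both removed and protected: {overlap}")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")


def _encode(man: pd.DataFrame, columns: list[str]) -> tuple[np.ndarray, list[str], dict[str, list[str]]]:
    """Design columns (no intercept) for the requested covariates; categorical
    ones are one-hot encoded dropping a reference level.  Returns the design,
    its column names, and a map covariate -> its design columns."""
    parts, names, owner = [], [], {}
    for c in columns:
        if c not in man.columns:
            raise ValueError(f"covariate {c!r} absent from manifest")
        col = man[c]
        if c in CATEGORICAL or col.dtype == object or str(col.dtype) == "category":
            dummies = pd.get_dummies(col.astype(str), prefix=c, drop_first=True)
            if dummies.shape[1] == 0:
                raise ValueError(f"covariate {c!r} has no variance")
            parts.append(dummies.to_numpy(dtype=float))
            owner[c] = list(dummies.columns)
            names.extend(dummies.columns)
        else:
            v = pd.to_numeric(col).to_numpy(dtype=float)
            if np.nanstd(v) == 0:
                raise ValueError(f"covariate {c!r} has zero variance")
            parts.append(v[:, None])
            owner[c] = [c]
            names.append(c)
    return np.hstack(parts), names, owner


def _masked_ols(X: np.ndarray, Y: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Per-column OLS of Y (n x p, NaN allowed, mask M) on design X (n x k),
    solved through per-protein normal equations so one call covers every
    missingness pattern.  Returns beta (p x k); NaN where singular."""
    Yz = np.where(M, Y, 0.0)
    # A[g] = X' diag(m_g) X ; b[g] = X' diag(m_g) y_g
    A = np.einsum("nk,np,nl->pkl", X, M.astype(float), X, optimize=True)
    b = np.einsum("nk,np->pk", X, Yz, optimize=True)
    p, k = b.shape
    beta = np.full((p, k), np.nan)
    # solve batched; fall back per-protein on singular systems
    try:
        beta = np.linalg.solve(A, b[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError:
        for g in range(p):
            try:
                beta[g] = np.linalg.solve(A[g], b[g])
            except np.linalg.LinAlgError:
                beta[g] = np.nan
    return beta


def bootstrap_regress(X: AbundanceMatrix, manifest: SampleManifest,
                      spec: RegressionSpec, _resample: bool = True
                      ) -> AbundanceMatrix:
    """Remove nuisance-covariate variance from a log2 abundance matrix.

    The subtraction uses, per protein and per removed covariate, the median
    coefficient over ``spec.n_bootstrap`` seeded resamples of samples with
    replacement; covariates are centered before subtraction so each protein's
    grand mean is preserved.  ``_resample=False`` with ``n_bootstrap=1`` is an
    internal hook equal to plain OLS residualisation.
    """
    X.require_tag("tampor_corrected", "log2")
    spec.validate()
    manifest.check_against(X)
    man = manifest.table.loc[X.sample_ids]

    all_covs = list(spec.covariates_to_remove) + list(spec.protected)
    D, names, owner = _encode(man, all_covs)
    n, k = D.shape
    design = np.hstack([np.ones((n, 1)), D])  # intercept first

    Y = X.values.to_numpy(dtype=float).T          # n x p
    M = np.isfinite(Y)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError("rank-deficient design after encoding")

    rng = np.random.default_rng(spec.seed)
    betas = np.empty((spec.n_bootstrap, Y.shape[1], design.shape[1]))
    for b in range(spec.n_bootstrap):
        idx = rng.integers(0, n, size=n) if _resample else np.arange(n)
        betas[b] = _masked_ols(design[idx], Y[idx], M[idx])
    med = np.nanmedian(betas, axis=0)             # p x (1 + k)

    # subtract only the removed covariates' centered contributions
    out = Y.copy()
    for c in spec.covariates_to_remove:
        for col in owner[c]:
            j = 1 + names.index(col)
            x = design[:, j]
            out = out - np.outer(x - x.mean(), med[:, j])
    res = pd.DataFrame(out.T, index=X.protein_ids, columns=X.sample_ids)
    log.info("bootstrap_regress: removed %s over %d resamples",
             spec.covariates_to_remove, spec.n_bootstrap)
    return X.with_values(res, scale_tag="regressed")


def variance_explained(X: AbundanceMatrix, manifest: SampleManifest,
                       factors: list[str]) -> pd.DataFrame:
    """Per-protein marginal R^2 of abundance on each factor alone.

    A single-factor least-squares fit per protein (categorical factors
    one-hot encoded); values in [0, 1].  Diagnostic companion to the cleanup
    steps — the median batch R^2 should fall across raw -> TAMPOR ->
    regressed.
    """
    manifest.check_against(X)
    man = manifest.table.loc[X.sample_ids]
    Y = X.values.to_numpy(dtype=float).T
    M = np.isfinite(Y)
    out = {}
    for f in factors:
        D, _, _ = _encode(man, [f])
        design = np.hstack([np.ones((len(man), 1)), D])
        beta = _masked_ols(design, Y, M)
        fit = design @ beta.T                      # n x p
        mean_y = np.where(M, Y, 0.0).sum(0) / M.sum(0)
        sse = np.nansum(np.where(M, (Y - fit) ** 2, 0.0), axis=0)
        sst = np.nansum(np.where(M, (Y - mean_y) ** 2, 0.0), axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = 1.0 - sse / sst
        out[f] = np.clip(r2, 0.0, 1.0)
    return pd.DataFrame(out, index=X.protein_ids)
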