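"""Cross-network module preservation with a permutation Zsummary.

Modules defined in a reference dataset (the vascular-enriched network) are
scored in a test dataset (e.g. a bulk-cortex proteome) on a reduced,
documented statistic battery: density (mean within-module |bicor| and mean
|kME| in the test data) and connectivity (correlation of intramodular
connectivity and of the within-module correlation entries between reference
and test).  Each statistic is standardised against random same-size gene
draws; Zdensity and Zconnectivity are the medians of their pairs and
Zsummary their mean.  Classification follows the usual thresholds:
Zsummary >= 10 highly preserved, >= 1.96 preserved, below that not
preserved (both inclusive).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import AbundanceMatrix
from .network import bicor_between, bicor_matrix, _zscore_impute

log = logging.getLogger(__name__)

MIN_SHARED = 5
Z_PRESERVED = 1.96
Z_HIGH = 10.0


@dataclass
class PreservationResult:
    module: int
    size: int
    mean_cor: float
    cor_kim: float
    cor_cor: float
    mean_kme: float
    z_mean_cor: float
    z_cor_kim: float
    z_cor_cor: float
    z_mean_kme: float
    z_density: float
    z_connectivity: float
    z_summary: float
    classification: str


def _module_stats(idx: np.ndarray, C_ref: np.ndarray, C_test: np.ndarray,
                  Z_test: np.ndarray) -> tuple[float, float, float, float]:
    """(meanCor, cor.kIM, cor.cor, meanKME) for one gene index set."""
    sub_ref = C_ref[np.ix_(idx, idx)]
    sub_test = C_test[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    off_ref, off_test = sub_ref[iu], sub_test[iu]
    mean_cor = float(np.nanmean(np.abs(off_test)))
    # intramodular connectivity: sum of |cor| to other members
    kim_ref = np.nansum(np.abs(sub_ref), axis=1) - 1.0
    kim_test = np.nansum(np.abs(sub_test), axis=1) - 1.0
    cor_kim = _safe_corr(kim_ref, kim_test)
    cor_cor = _safe_corr(off_ref, off_test)
    # eigenprotein of the module in the test data, then mean |kME|
    sub_z = Z_test[idx]
    _, _, Vt = np.linalg.svd(sub_z, full_matrices=False)
    me = Vt[0][None, :]
    kme = bicor_between(sub_z, me)[:, 0]
    mean_kme = float(np.nanmean(np.abs(kme)))
    return mean_cor, cor_kim, cor_cor, mean_kme


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        return np.nan
    return float(np.corrcoef(x[ok], y[ok])[0, 1])


def classify(z_summary: float) -> str:
    if not np.isfinite(z_summary):
        return "undefined"
    if z_summary >= Z_HIGH:
        return "highly_preserved"
    if z_summary >= Z_PRESERVED:
        return "preserved"
    return "not_preserved"


def module_preservation(ref: AbundanceMatrix, test: AbundanceMatrix,
                        labels: pd.Series, n_perm: int = 500,
                        seed: int = 0) -> pd.DataFrame:
    """Score reference-defined modules in a test dataset.

    Gene identifiers are intersected; modules with fewer than 5 shared genes
    are skipped.  The null draws ``n_perm`` random same-size gene sets from
    the shared genes and recomputes every statistic; per-statistic
    Z = (obs - null mean)/null sd, with zero-variance statistics dropped
    from their median.  Returns one row per module plus classification.
    """
    shared = ref.protein_ids.intersection(test.protein_ids)
    if len(shared) < MIN_SHARED:
        raise ValueError("fewer than 5 shared genes between datasets")
    ref_s = ref.subset_proteins(shared)
    test_s = test.subset_proteins(shared)
    labs = labels.reindex(shared).fillna(0).astype(int)

    C_ref = bicor_matrix(ref_s).to_numpy()
    C_test = bicor_matrix(test_s).to_numpy()
    Z_test = _zscore_impute(test_s.values.to_numpy(dtype=float))

    rng = np.random.default_rng(seed)
    stat_names = ("mean_cor", "cor_kim", "cor_cor", "mean_kme")
    rows = []
    for m in sorted(x for x in labs.unique() if x > 0):
        idx = np.where((labs == m).to_numpy())[0]
        if len(idx) < MIN_SHARED:
            log.warning("module %s: <%d shared genes; skipped", m, MIN_SHARED)
            continue
        obs = _module_stats(idx, C_ref, C_test, Z_test)
        null = np.empty((n_perm, 4))
        for i in range(n_perm):
            ridx = rng.choice(len(shared), size=len(idx), replace=False)
            null[i] = _module_stats(ridx, C_ref, C_test, Z_test)
        mu = np.nanmean(null, axis=0)
        sd = np.nanstd(null, axis=0, ddof=1)
        z = np.full(4, np.nan)
        for s in range(4):
            if sd[s] > 0 and np.isfinite(obs[s]):
                z[s] = (obs[s] - mu[s]) / sd[s]
            else:
                log.warning("module %s: degenerate null for %s; dropped",
                            m, stat_names[s])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            z_density = float(np.nanmedian([z[0], z[3]]))
            z_conn = float(np.nanmedian([z[1], z[2]]))
            # composite over whichever halves are defined (a degenerate null,
            # e.g. test == reference, can drop a whole pair)
            z_summary = float(np.nanmean([z_density, z_conn]))
        rows.append({"module": m, "size": len(idx),
                     "mean_cor": obs[0], "cor_kim": obs[1],
                     "cor_cor": obs[2], "mean_kme": obs[3],
                     "z_mean_cor": z[0], "z_cor_kim": z[1],
                     "z_cor_cor": z[2], "z_mean_kme": z[3],
                     "z_density": z_density, "z_connectivity": z_conn,
                     "z_summary": z_summary,
                     "classification": classify(z_summary)})
    return pd.DataFrame(rows)
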