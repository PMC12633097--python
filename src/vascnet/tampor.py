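"""TAMPOR batch correction: median polish of sample/GIS ratios.

Multiplexed TMT batches are corrected by (1) expressing every sample as a
log2 ratio to a within-batch denominator — the batch's pooled
global-internal-standard (GIS) channels, or all non-GIS channels when
``use_all_non_gis`` — and (2) iteratively median-centering protein rows
(over the denominator-defining samples) and sample columns until both sets
of medians vanish.  All arithmetic is additive in log2, equivalent to a
multiplicative polish of the ratio matrix and exactly idempotent at
convergence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import AbundanceMatrix, SampleManifest

log = logging.getLogger(__name__)


@dataclass
class TamporState:
    """Per-run diagnostics: iteration count and the magnitude of the largest
    row/column median at each sweep (nonincreasing after the first)."""

    use_all_non_gis: bool
    iteration: int = 0
    max_abs_row_median: list[float] = field(default_factory=list)
    max_abs_col_median: list[float] = field(default_factory=list)
    converged: bool = False
    dropped_proteins: list[str] = field(default_factory=list)


def tampor_correct(X: AbundanceMatrix, manifest: SampleManifest,
                   use_all_non_gis: bool = False, tol: float = 1e-8,
                   max_iterations: int = 250, keep_gis: bool = False
                   ) -> tuple[AbundanceMatrix, TamporState]:
    """Batch-correct a log2 abundance matrix by median polish of ratios.

    Parameters
    ----------
    use_all_non_gis
        If False (default) the ratio denominator of batch b is the median
        over b's GIS channels; if True, over all of b's non-GIS channels.
    keep_gis
        GIS columns are corrected alongside but excluded from the output
        unless requested.

    Returns the corrected matrix (scale_tag ``tampor_corrected``) and a
    :class:`TamporState` with per-iteration diagnostics.  Proteins lacking a
    usable denominator in any batch are dropped with a warning.
    """
    X.require_tag("log2")
    manifest.check_against(X, require_gis=not use_all_non_gis)
    man = manifest.table.loc[X.sample_ids]
    batches = man["batch"].to_numpy()
    is_gis = man["is_gis"].to_numpy()

    vals = X.values.to_numpy(dtype=float).copy()
    sample_ids = list(X.sample_ids)

    # denominator-defining columns
    denom_cols = ~is_gis if use_all_non_gis else is_gis

    # step 1: per-batch log2 ratio to the denominator median
    for b in pd.unique(batches):
        in_b = batches == b
        dcols = in_b & denom_cols
        if not dcols.any():
            raise ValueError(f"batch {b!r} has no denominator samples")
        with warnings.catch_warnings():
            # all-NaN rows are dropped right below
            warnings.simplefilter("ignore", RuntimeWarning)
            D = np.nanmedian(vals[:, dcols], axis=1)
        vals[:, in_b] = vals[:, in_b] - D[:, None]

    # drop proteins with no denominator in some batch (NaN D propagates to
    # the whole batch) or missing everywhere in the centering sample set
    all_nan_row = np.all(np.isnan(vals), axis=1)
    no_denom = np.zeros(vals.shape[0], dtype=bool)
    for b in pd.unique(batches):
        dcols = (batches == b) & denom_cols
        no_denom |= np.all(np.isnan(vals[:, dcols]), axis=1)
    drop = all_nan_row | no_denom
    dropped = [p for p, d in zip(X.protein_ids, drop) if d]
    if dropped:
        log.warning("tampor: dropping %d proteins with no usable denominator",
                    len(dropped))
    vals = vals[~drop]
    proteins = X.protein_ids[~drop]

    state = TamporState(use_all_non_gis=use_all_non_gis,
                        dropped_proteins=dropped)

    # step 2: iterative two-way median centering
    for it in range(1, max_iterations + 1):
        with np.errstate(invalid="ignore", all="ignore"):
            row_med = np.nanmedian(vals[:, denom_cols], axis=1)
        row_med = np.where(np.isnan(row_med), 0.0, row_med)
        vals = vals - row_med[:, None]
        with np.errstate(invalid="ignore", all="ignore"):
            col_med = np.nanmedian(vals, axis=0)
        col_med = np.where(np.isnan(col_med), 0.0, col_med)
        vals = vals - col_med[None, :]

        state.iteration = it
        state.max_abs_row_median.append(float(np.max(np.abs(row_med), initial=0.0)))
        state.max_abs_col_median.append(float(np.max(np.abs(col_med), initial=0.0)))

        # convergence check on the *post-centering* medians
        with np.errstate(invalid="ignore", all="ignore"):
            r = np.nanmedian(vals[:, denom_cols], axis=1)
            c = np.nanmedian(vals, axis=0)
        r = np.where(np.isnan(r), 0.0, r)
        resid = max(float(np.max(np.abs(r), initial=0.0)),
                    float(np.max(np.abs(c), initial=0.0)))
        if resid < tol:
            state.converged = True
            break

    log.info("tampor: %s after %d iterations (useAllNonGIS=%s)",
             "converged" if state.converged else "NOT converged",
             state.iteration, use_all_non_gis)

    out = pd.DataFrame(vals, index=proteins, columns=sample_ids)
    if not keep_gis:
        out = out.loc[:, [s for s, g in zip(sample_ids, is_gis) if not g]]
    corrected = AbundanceMatrix(values=out, scale_tag="tampor_corrected")
    return corrected, state
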