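"""Module-level enrichment statistics.

Two machineries: (1) a permutation mean-statistic test — each module's mean
transformed p-value (default -log10 p, so larger = more significant) is
compared with the distribution of means over random same-size gene draws
from the measured background, yielding a Z score and an exact permutation
p-value; (2) one-sided Fisher exact (hypergeometric upper-tail) overlap of
module membership with gene sets (cell-type markers, ontologies) read from
GMT, BH-corrected across the module x set grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .association import adjust_pvalues

log = logging.getLogger(__name__)

TRANSFORMS = ("neglog10p", "raw_p", "signed_logp")

#: exhaustive enumeration kicks in when the number of distinct subsets is
#: at most this multiple of n_perm
EXHAUSTIVE_FACTOR = 10


@dataclass
class EnrichmentReport:
    module: int
    n_genes_with_stats: int
    observed: float
    perm_mean: float
    perm_sd: float
    z: float
    p_perm: float
    p_fdr: float
    n_perm: int
    transform: str
    degenerate: bool = False
    exhaustive: bool = False


def _transform_stats(p: np.ndarray, transform: str,
                     signs: np.ndarray | None) -> np.ndarray:
    if transform == "neglog10p":
        return -np.log10(np.maximum(p, 1e-300))
    if transform == "raw_p":
        # negated so that "larger = more enriched" holds for every transform
        return -p
    if transform == "signed_logp":
        if signs is None:
            raise ValueError("signed_logp requires per-gene signs")
        return np.sign(signs) * -np.log10(np.maximum(p, 1e-300))
    raise ValueError(f"unknown transform {transform!r}")


def permutation_module_enrichment(gene_stats: pd.Series, labels: pd.Series,
                                  n_perm: int = 10000,
                                  transform: str = "neglog10p",
                                  seed: int = 0,
                                  signs: pd.Series | None = None
                                  ) -> pd.DataFrame:
    """Permutation mean-statistic module enrichment.

    The background is every gene carrying both a statistic and a label (grey
    genes count toward the background but form no tested module).  For each
    module, T = mean transformed statistic of its genes; the null is the
    mean over random same-size draws without replacement from the
    background; Z = (T - mean T*)/sd T* and the one-sided exact permutation
    p is (#{T* >= T} + 1)/(n_perm + 1).  When the number of distinct
    subsets is small (<= 10 * n_perm) the null is enumerated exhaustively.
    BH correction runs across modules.
    """
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    common = gene_stats.index.intersection(labels.index)
    stats = gene_stats.loc[common].dropna()
    labs = labels.loc[stats.index]
    bg = _transform_stats(stats.to_numpy(dtype=float), transform,
                          None if signs is None
                          else signs.reindex(stats.index).to_numpy(dtype=float))
    n_bg = len(bg)
    rng = np.random.default_rng(seed)
    rows = []
    for m in sorted(x for x in labs.unique() if x > 0):
        in_m = (labs == m).to_numpy()
        k = int(in_m.sum())
        if k < 2:
            log.warning("module %s: fewer than 2 genes with statistics; skipped", m)
            continue
        T = float(bg[in_m].mean())
        n_subsets = comb(n_bg, k)
        exhaustive = n_subsets <= EXHAUSTIVE_FACTOR * n_perm
        if exhaustive:
            T_null = np.fromiter(
                (bg[list(c)].mean() for c in combinations(range(n_bg), k)),
                dtype=float, count=n_subsets)
        else:
            draws = np.empty((n_perm, k), dtype=int)
            for i in range(n_perm):
                draws[i] = rng.choice(n_bg, size=k, replace=False)
            T_null = bg[draws].mean(axis=1)
        mu, sd = float(T_null.mean()), float(T_null.std(ddof=1))
        degenerate = not (sd > 0)
        if degenerate:
            z, p = np.nan, 1.0
        else:
            z = (T - mu) / sd
            b = int((T_null >= T).sum())
            p = (b + 1) / (len(T_null) + 1)
        rows.append({"module": m, "n_genes_with_stats": k, "observed": T,
                     "perm_mean": mu, "perm_sd": sd, "z": z, "p_perm": p,
                     "n_perm": len(T_null), "transform": transform,
                     "degenerate": degenerate, "exhaustive": exhaustive})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_fdr"] = adjust_pvalues(df["p_perm"].to_numpy(), "BH")
        for level in (0.05, 0.10):
            sig = df.loc[df["p_fdr"] <= level, "z"]
            df.attrs[f"z_threshold_fdr{int(level * 100)}"] = (
                float(sig.min()) if len(sig) else np.nan)
    return df


def fisher_set_enrichment(labels: pd.Series, sets: dict[str, list[str]],
                          background: list[str] | None = None) -> pd.DataFrame:
    """One-sided Fisher exact (hypergeometric upper-tail) enrichment of each
    module's members in each gene set, BH-corrected across the full
    module x set grid.  Sets are intersected with the background first; the
    odds ratio is the sample ad/bc (inf when bc = 0 and ad > 0)."""
    if background is None:
        background = list(labels.index)
    bg = pd.Index(background).unique()
    if len(bg) == 0:
        raise ValueError("empty background")
    labs = labels.reindex(bg).fillna(0).astype(int)
    rows = []
    for set_name, members in sets.items():
        set_in_bg = bg.intersection(pd.Index(members).unique())
        if len(set_in_bg) == 0:
            log.warning("set %r disjoint from background; skipped", set_name)
            continue
        in_set = labs.index.isin(set_in_bg)
        for m in sorted(x for x in labs.unique() if x > 0):
            in_mod = (labs == m).to_numpy()
            a = int((in_mod & in_set).sum())          # overlap
            b = int((in_mod & ~in_set).sum())
            c = int((~in_mod & in_set).sum())
            d = int((~in_mod & ~in_set).sum())
            # P(overlap >= a) under hypergeometric with these margins
            p = float(hypergeom.sf(a - 1, len(bg), a + c, a + b))
            odds = (a * d / (b * c)) if b * c > 0 else (np.inf if a * d > 0 else 0.0)
            rows.append({"module": m, "set": set_name, "overlap": a,
                         "module_size": a + b, "set_size": a + c,
                         "background_size": len(bg), "odds_ratio": odds,
                         "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_bh"] = adjust_pvalues(df["p"].to_numpy(), "BH")
    return df
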