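"""Trait-association layer: eigenprotein/trait correlations, group
differential abundance, and proteome-wide regression scans (linear,
logistic, ordinal proportional-odds) with Bonferroni or Benjamini-Hochberg
multiplicity control.

Direction convention for the regression scans: the protein abundance is the
predictor (exposure) and the pathology the outcome, so a positive beta means
higher abundance accompanies more severe pathology.  Protein abundances are
standardised before logistic/ordinal fits for numerical stability; betas are
reported on that scale.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.api import Logit, OLS, add_constant
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.stats.multitest import multipletests

from .datatypes import AbundanceMatrix, SampleManifest
from .network import bicor_between, correlation_pvalue

log = logging.getLogger(__name__)

TINY_P = 1e-300  # reporting floor for p-values below machine representation


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment: Bonferroni (min(1, p*m)) or
    Benjamini-Hochberg step-up with enforced monotonicity."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    method = method.upper()
    if method == "BONFERRONI":
        return np.minimum(p * len(p), 1.0)
    if method == "BH":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment method {method!r}")


def _finish(df: pd.DataFrame, adjust: str) -> pd.DataFrame:
    ok = df["p"].notna()
    df["p_adj"] = np.nan
    if ok.any():
        df.loc[ok, "p_adj"] = adjust_pvalues(df.loc[ok, "p"].to_numpy(), adjust)
    df.attrs["adjust_method"] = adjust
    return df


# ---------------------------------------------------------------------------
# module level

def me_trait_association(ME: pd.DataFrame, manifest: SampleManifest,
                         traits: list[str]) -> pd.DataFrame:
    """bicor of every module eigenprotein with every (numeric-coded) trait,
    with Student-t p-values; complete-case per trait."""
    man = manifest.table.loc[ME.columns]
    rows = []
    for trait in traits:
        y = pd.to_numeric(man[trait], errors="coerce").to_numpy(dtype=float)
        if np.nanstd(y) == 0:
            raise ValueError(f"trait {trait!r} is constant")
        n_used = int(np.isfinite(y).sum())
        r = bicor_between(ME.to_numpy(), y[None, :])[:, 0]
        p = correlation_pvalue(r, n_used)
        for m, rm, pm in zip(ME.index, r, p):
            rows.append({"unit": "module", "id": m, "trait": trait,
                         "model": "bicor", "effect": rm,
                         "p": max(pm, TINY_P) if np.isfinite(pm) else np.nan,
                         "n_used": n_used})
    df = pd.DataFrame(rows)
    df.attrs["model"] = "bicor"
    return df


def me_trait_heatmap(assoc: pd.DataFrame, path, p_annot: float = 0.05) -> None:
    """Two-colour (blue/red) heatmap of module x trait correlations with
    p-values annotated where p < ``p_annot``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    r = assoc.pivot(index="id", columns="trait", values="effect")
    p = assoc.pivot(index="id", columns="trait", values="p")
    fig, ax = plt.subplots(figsize=(1.2 * r.shape[1] + 2, 0.4 * r.shape[0] + 2))
    im = ax.imshow(r.to_numpy(), cmap="bwr", vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(r.shape[1]), r.columns, rotation=45, ha="right")
    ax.set_yticks(range(r.shape[0]), r.index)
    for i in range(r.shape[0]):
        for j in range(r.shape[1]):
            if p.iloc[i, j] < p_annot:
                ax.text(j, i, f"{p.iloc[i, j]:.1e}", ha="center", va="center",
                        fontsize=6)
    fig.colorbar(im, ax=ax, label="bicor")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# group differential abundance

TUKEY_FALLBACK_P = 10 ** -8.5  # below this, Tukey loses accuracy -> Bonferroni


def differential_abundance(X: AbundanceMatrix, manifest: SampleManifest,
                           group_col: str = "group", mode: str = "ttest",
                           adjust: str = "BH") -> pd.DataFrame:
    """Per-protein group comparison.

    ``ttest``: Welch two-sample t per protein, effect = difference of group
    means (log2 fold change, group2 - group1 in sorted label order).
    ``anova_tukey``: one-way ANOVA with Tukey HSD pairwise p-values; Tukey
    p-values below 1e-8.5 are replaced by the Bonferroni-corrected pairwise
    (Welch) p for that comparison.  Proteins with any group below 2
    non-missing values are skipped with a flag.
    """
    man = manifest.table.loc[X.sample_ids]
    groups = man[group_col].dropna()
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    if mode == "ttest" and len(levels) != 2:
        raise ValueError("ttest mode requires exactly 2 groups")
    idx = {lev: X.sample_ids.get_indexer(groups.index[groups == lev])
           for lev in levels}
    vals = X.values.to_numpy(dtype=float)
    rows = []
    for gi, prot in enumerate(X.protein_ids):
        by_group = [vals[gi, idx[lev]] for lev in levels]
        by_group = [v[np.isfinite(v)] for v in by_group]
        if any(len(v) < 2 for v in by_group):
            rows.append({"unit": "protein", "id": prot, "trait": group_col,
                         "model": mode, "comparison": None, "effect": np.nan,
                         "p": np.nan, "n_used": 0, "flag": "too_few_obs"})
            continue
        n_used = int(sum(len(v) for v in by_group))
        if mode == "ttest":
            a, b = by_group
            tt = stats.ttest_ind(b, a, equal_var=False)
            rows.append({"unit": "protein", "id": prot, "trait": group_col,
                         "model": "ttest",
                         "comparison": f"{levels[1]}-{levels[0]}",
                         "effect": float(b.mean() - a.mean()),
                         "p": float(tt.pvalue), "n_used": n_used, "flag": ""})
        elif mode == "anova_tukey":
            F, p_anova = stats.f_oneway(*by_group)
            tk = stats.tukey_hsd(*by_group)
            for i in range(len(levels)):
                for j in range(i + 1, len(levels)):
                    p_t = float(tk.pvalue[i, j])
                    flag = ""
                    if p_t < TUKEY_FALLBACK_P:
                        n_cmp = len(levels) * (len(levels) - 1) // 2
                        p_w = stats.ttest_ind(by_group[i], by_group[j],
                                              equal_var=False).pvalue
                        p_t = min(1.0, float(p_w) * n_cmp)
                        flag = "bonferroni_fallback"
                    rows.append({"unit": "protein", "id": prot,
                                 "trait": group_col, "model": "anova_tukey",
                                 "comparison": f"{levels[j]}-{levels[i]}",
                                 "effect": float(by_group[j].mean()
                                                 - by_group[i].mean()),
                                 "p": p_t, "anova_p": float(p_anova),
                                 "n_used": n_used, "flag": flag})
        else:
            raise ValueError(f"unknown mode {mode!r}")
    df = pd.DataFrame(rows)
    return _finish(df, adjust)


# ---------------------------------------------------------------------------
# proteome-wide regression scans

def _design(man: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    cols = {}
    for c in covariates:
        col = man[c]
        if col.dtype == object or str(col.dtype) == "category":
            dummies = pd.get_dummies(col.astype(str), prefix=c, drop_first=True)
            for d in dummies.columns:
                cols[d] = dummies[d].astype(float)
        else:
            cols[c] = pd.to_numeric(col).astype(float)
    return pd.DataFrame(cols, index=man.index)


def proteomewide_scan(X: AbundanceMatrix, manifest: SampleManifest,
                      outcome: str, model: str = "linear",
                      covariates: list[str] | None = None,
                      adjust: str = "bonferroni") -> pd.DataFrame:
    """Per-protein regression of the outcome on protein abundance plus
    covariates.

    ``linear``: OLS for continuous outcomes (e.g. WMH burden).
    ``logistic``: binary outcomes (microbleeds, infarcts).
    ``ordinal``: proportional-odds logit for ordered 0..3 severity (CAA).

    Complete-case per scan; protein abundance standardised for the
    logistic/ordinal fits.  Returns Wald beta/p per protein with the
    adjusted p and, for Bonferroni, the explicit 0.05/m cutoff in
    ``df.attrs['bonferroni_cutoff']``.
    """
    covariates = covariates or []
    man = manifest.table.loc[X.sample_ids]
    y_all = pd.to_numeric(man[outcome], errors="coerce")
    D = _design(man, covariates) if covariates else pd.DataFrame(index=man.index)
    vals = X.values.to_numpy(dtype=float)
    base_ok = y_all.notna().to_numpy()
    for c in D.columns:
        base_ok &= D[c].notna().to_numpy()
    rows = []
    for gi, prot in enumerate(X.protein_ids):
        x = vals[gi]
        ok = base_ok & np.isfinite(x)
        n_used = int(ok.sum())
        out = {"unit": "protein", "id": prot, "trait": outcome, "model": model,
               "effect": np.nan, "p": np.nan, "n_used": n_used, "flag": ""}
        if n_used < len(D.columns) + 3:
            out["flag"] = "too_few_obs"
            rows.append(out)
            continue
        xs = x[ok]
        if model in ("logistic", "ordinal"):
            sd = xs.std(ddof=1)
            xs = (xs - xs.mean()) / (sd if sd > 0 else 1.0)
        exog = np.column_stack([xs] + [D[c].to_numpy()[ok] for c in D.columns])
        y = y_all.to_numpy(dtype=float)[ok]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if model == "linear":
                    fit = OLS(y, add_constant(exog, has_constant="add")).fit()
                    out["effect"], out["p"] = fit.params[1], fit.pvalues[1]
                elif model == "logistic":
                    fit = Logit(y, add_constant(exog, has_constant="add")
                                ).fit(disp=0, maxiter=100)
                    if not fit.mle_retvals.get("converged", True):
                        raise RuntimeError("no convergence")
                    out["effect"], out["p"] = fit.params[1], fit.pvalues[1]
                elif model == "ordinal":
                    fit = OrderedModel(y.astype(int), exog, distr="logit").fit(
                        method="lbfgs", disp=0, maxiter=200, pgtol=1e-8)
                    out["effect"], out["p"] = fit.params[0], fit.pvalues[0]
                else:
                    raise ValueError(f"unknown model {model!r}")
        except (Exception,) as exc:  # separation / non-convergence
            out["flag"] = f"fit_failed:{type(exc).__name__}"
        if np.isfinite(out["p"]):
            out["p"] = max(float(out["p"]), TINY_P)
        rows.append(out)
    df = pd.DataFrame(rows)
    m = int(df["p"].notna().sum())
    df = _finish(df, adjust)
    df.attrs["bonferroni_cutoff"] = 0.05 / m if m else np.nan
    df.attrs["n_tested"] = m
    return df


def protein_trait_bicor(X: AbundanceMatrix, manifest: SampleManifest,
                        trait: str, adjust: str = "BH") -> pd.DataFrame:
    """Per-protein bicor with a numeric trait plus Student-t p; the positive
    and negative significant sets at p < 0.05 are tallied in ``attrs``."""
    man = manifest.table.loc[X.sample_ids]
    y = pd.to_numeric(man[trait], errors="coerce").to_numpy(dtype=float)
    M = np.isfinite(X.values.to_numpy()) & np.isfinite(y)[None, :]
    n_used = M.sum(axis=1)
    r = bicor_between(X.values, y[None, :])[:, 0]
    p = correlation_pvalue(r, n_used)
    df = pd.DataFrame({"unit": "protein", "id": X.protein_ids, "trait": trait,
                       "model": "bicor", "effect": r,
                       "p": np.where(np.isfinite(p), np.maximum(p, TINY_P), np.nan),
                       "n_used": n_used})
    df = _finish(df, adjust)
    sig = df["p"] < 0.05
    df.attrs["n_positive_significant"] = int((sig & (df["effect"] > 0)).sum())
    df.attrs["n_negative_significant"] = int((sig & (df["effect"] < 0)).sum())
    return df


def volcano_plot(assoc: pd.DataFrame, path, p_col: str = "p",
                 effect_col: str = "effect", alpha: float = 0.05) -> None:
    """Volcano export: effect vs -log10 p, significant points coloured."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    eff = assoc[effect_col].to_numpy(dtype=float)
    p = assoc[p_col].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        nlp = -np.log10(p)
    up = (p < alpha) & (eff > 0)
    dn = (p < alpha) & (eff < 0)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(eff, nlp, s=6, c="grey", alpha=0.5)
    ax.scatter(eff[up], nlp[up], s=6, c="red")
    ax.scatter(eff[dn], nlp[dn], s=6, c="blue")
    ax.set_xlabel(effect_col)
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
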