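"""Signed weighted co-expression network construction and module refinement.

The chain is the standard weighted-correlation-network recipe, robustified
with the biweight midcorrelation (bicor): bicor -> signed soft-threshold
adjacency ((1+C)/2)^beta -> topological overlap (TOM, mean denominator) ->
average-linkage clustering of 1-TOM with an adaptive cut -> module
eigenproteins (first principal component of each module's standardised
profiles) -> kME membership table -> iterative three-rule kME reassignment
and eigenprotein-correlation module merging.

Tree cutting uses a simplified quantile cut (q = 0.99 - 0.02*deep_split of
the merge heights) with small-branch dissolution and a PAM-like stage that
respects the dendrogram; the target property is planted-module recovery
rather than label-identical agreement with any particular reference
implementation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import t as t_dist

from .datatypes import AbundanceMatrix

log = logging.getLogger(__name__)

MIN_PAIRWISE_OBS = 4  # fewer pairwise-complete observations -> undefined entry


@dataclass
class NetworkParams:
    """Network construction parameters (defaults: signed network, power 8,
    deepSplit 3, minimum module size 10, merge cut height 0.07, mean TOM
    denominator, PAM staging, kME rules gap 0.10 / floor 0.30 / 30 sweeps)."""

    soft_power: float = 8.0
    deep_split: int = 3
    min_module_size: int = 10
    merge_cut_height: float = 0.07
    tom_denom: str = "mean"
    network_type: str = "signed"
    pam_stage: bool = True
    pam_respects_dendro: bool = True
    reassign_kme_gap: float = 0.10
    kme_assign_floor: float = 0.30
    max_reassign_iterations: int = 30

    def validate(self) -> None:
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        if not (0.0 < self.merge_cut_height < 1.0):
            raise ValueError("merge_cut_height must lie in (0,1)")
        if not (0.0 < self.kme_assign_floor < 1.0):
            raise ValueError("kme_assign_floor must lie in (0,1)")
        if self.deep_split not in (0, 1, 2, 3, 4):
            raise ValueError("deep_split must be in 0..4")
        if self.tom_denom not in ("mean", "min"):
            raise ValueError("tom_denom must be 'mean' or 'min'")
        if self.network_type != "signed":
            raise ValueError("only the signed network type is implemented")


@dataclass
class NetworkModel:
    """Fitted network: correlation/adjacency/TOM, dendrogram, final labels
    (0 = grey/unassigned, modules numbered 1..K by decreasing size),
    eigenproteins, per-module variance explained and the kME table."""

    correlation: pd.DataFrame
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    dendrogram: np.ndarray
    labels: pd.Series
    eigenproteins: pd.DataFrame          # modules x samples
    var_explained: pd.Series
    kme: pd.DataFrame                    # proteins x modules
    params: NetworkParams
    reassign_iterations: int = 0
    reassign_converged: bool = True

    @property
    def module_sizes(self) -> pd.Series:
        counts = self.labels[self.labels > 0].value_counts().sort_index()
        return counts


# ---------------------------------------------------------------------------
# biweight midcorrelation

def _bicor_prep(vals: np.ndarray):
    """Per-row biweight vectors on observed entries.

    Returns (a, mask, bad) where a holds w*(x-med) with NaN->0, and ``bad``
    marks rows whose MAD is zero (Pearson fallback applies to their pairs).
    """
    M = np.isfinite(vals)
    med = np.nanmedian(vals, axis=1, keepdims=True)
    mad = np.nanmedian(np.abs(vals - med), axis=1, keepdims=True)
    bad = (mad[:, 0] == 0) | ~np.isfinite(mad[:, 0])
    with np.errstate(invalid="ignore", divide="ignore"):
        u = (vals - med) / (9.0 * mad)
        w = (1.0 - u ** 2) ** 2 * (np.abs(u) < 1.0)
        a = w * (vals - med)
    a = np.where(M, a, 0.0)
    a[~np.isfinite(a)] = 0.0
    return a, M, bad


def _pearson_prep(vals: np.ndarray):
    M = np.isfinite(vals)
    mean = np.nanmean(vals, axis=1, keepdims=True)
    a = np.where(M, vals - mean, 0.0)
    return a, M


def _cross(a1, M1, a2, M2):
    """Normalised cross products with pairwise-complete denominators."""
    N = a1 @ a2.T
    S1 = (a1 ** 2) @ M2.T
    S2 = M1 @ (a2 ** 2).T
    with np.errstate(invalid="ignore", divide="ignore"):
        C = N / np.sqrt(S1 * S2)
    counts = M1.astype(float) @ M2.T.astype(float)
    C[counts < MIN_PAIRWISE_OBS] = np.nan
    return np.clip(C, -1.0, 1.0)


def bicor_between(X: np.ndarray | pd.DataFrame, Y: np.ndarray | pd.DataFrame
                  ) -> np.ndarray:
    """Biweight midcorrelation between the rows of X and the rows of Y
    (pairwise-complete).  Rows with zero MAD fall back to Pearson for every
    pair they participate in."""
    Xv = np.asarray(X, dtype=float)
    Yv = np.asarray(Y, dtype=float)
    a1, M1, bad1 = _bicor_prep(Xv)
    a2, M2, bad2 = _bicor_prep(Yv)
    C = _cross(a1, M1, a2, M2)
    if bad1.any() or bad2.any():
        p1, _ = _pearson_prep(Xv)
        p2, _ = _pearson_prep(Yv)
        P = _cross(p1, M1, p2, M2)
        C[bad1, :] = P[bad1, :]
        C[:, bad2] = P[:, bad2]
    return C


def bicor_matrix(X: AbundanceMatrix) -> pd.DataFrame:
    """Protein x protein biweight midcorrelation (pairwise-complete, with
    per-row Pearson fallback where the MAD vanishes); diagonal exactly 1."""
    if X.n_samples < MIN_PAIRWISE_OBS:
        raise ValueError(f"need >= {MIN_PAIRWISE_OBS} samples for bicor")
    C = bicor_between(X.values, X.values)
    np.fill_diagonal(C, 1.0)
    C = (C + C.T) / 2.0  # enforce exact symmetry against FP round-off
    return pd.DataFrame(C, index=X.protein_ids, columns=X.protein_ids)


def bicor(x, y) -> float:
    """Biweight midcorrelation of two vectors (pairwise-complete)."""
    return float(bicor_between(np.asarray(x, dtype=float)[None, :],
                               np.asarray(y, dtype=float)[None, :])[0, 0])


def correlation_pvalue(r, n):
    """Two-sided Student-t p-value for a correlation: t = r*sqrt((n-2)/(1-r^2))."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    n = np.asarray(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * t_dist.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return p


# ---------------------------------------------------------------------------
# adjacency and topological overlap

def signed_adjacency(C: pd.DataFrame | np.ndarray, beta: float = 8.0):
    """Signed soft-threshold adjacency A_ij = ((1 + C_ij)/2)^beta, diagonal 1;
    undefined correlations become adjacency 0."""
    Cv = np.asarray(C, dtype=float)
    und = ~np.isfinite(Cv)
    if und.any():
        log.warning("signed_adjacency: %d undefined correlation entries -> 0",
                    int(und.sum()) - int(np.isnan(np.diag(Cv)).sum()))
    A = ((1.0 + np.where(und, -1.0, Cv)) / 2.0) ** beta
    np.fill_diagonal(A, 1.0)
    if isinstance(C, pd.DataFrame):
        return pd.DataFrame(A, index=C.index, columns=C.columns)
    return A


def tom_similarity(A: pd.DataFrame | np.ndarray, denom: str = "mean"):
    """Topological overlap: TOM_ij = (sum_u A_iu A_uj + A_ij) /
    (f(k_i,k_j) - A_ij + 1), with f = mean or min of the connectivities
    k_i = sum_{u != i} A_iu; TOM_ii = 1."""
    Av = np.asarray(A, dtype=float)
    k = Av.sum(axis=1) - np.diag(Av)
    # shared-neighbour term excluding i and j themselves (diag of A is 1)
    num = Av @ Av - Av * np.diag(Av)[None, :] - np.diag(Av)[:, None] * Av + Av
    if denom == "mean":
        f = (k[:, None] + k[None, :]) / 2.0
    elif denom == "min":
        f = np.minimum(k[:, None], k[None, :])
    else:
        raise ValueError("denom must be 'mean' or 'min'")
    with np.errstate(invalid="ignore", divide="ignore"):
        T = num / (f - Av + 1.0)
    np.fill_diagonal(T, 1.0)
    T = np.clip((T + T.T) / 2.0, 0.0, 1.0)
    if isinstance(A, pd.DataFrame):
        return pd.DataFrame(T, index=A.index, columns=A.columns)
    return T


# ---------------------------------------------------------------------------
# module detection

def _dendro_allowed_modules(Z: np.ndarray, labels: np.ndarray) -> list[set]:
    """For each unassigned leaf, the set of modules present in the smallest
    dendrogram clade containing it and at least one assigned leaf."""
    n = len(labels)
    modules_of = [({int(l)} if l > 0 else set()) for l in labels]
    pending: list[list[int]] = [([i] if labels[i] == 0 else []) for i in range(n)]
    allowed: list[set] = [set() for _ in range(n)]
    for row in range(Z.shape[0]):
        a, b = int(Z[row, 0]), int(Z[row, 1])
        mods = modules_of[a] | modules_of[b]
        pend = pending[a] + pending[b]
        if mods and pend:
            for leaf in pend:
                allowed[leaf] = set(mods)
            pend = []
        modules_of.append(mods)
        pending.append(pend)
        # release children storage
        modules_of[a] = modules_of[b] = set()
        pending[a] = pending[b] = []
    return allowed


def _subtree_nodes(children: np.ndarray, node: int, n_leaves: int):
    """Leaves and internal nodes of the subtree rooted at ``node``."""
    leaves, internal = [], []
    stack = [node]
    while stack:
        v = stack.pop()
        if v < n_leaves:
            leaves.append(v)
        else:
            internal.append(v)
            stack.extend(children[v - n_leaves])
    return leaves, internal


def _cut_node(children: np.ndarray, height: np.ndarray, node: int,
              n_leaves: int, t: float) -> list[int]:
    """Maximal descendants of ``node`` whose merge height is <= t."""
    out, stack = [], [node]
    while stack:
        v = stack.pop()
        if v >= n_leaves and height[v] > t:
            stack.extend(children[v - n_leaves])
        else:
            out.append(v)
    return out


def detect_modules(TOM: pd.DataFrame, params: NetworkParams
                   ) -> tuple[np.ndarray, pd.Series]:
    """Average-linkage clustering of 1-TOM with a recursive quantile cut,
    dissolution of branches below the minimum size, and an optional
    PAM stage that attaches unassigned proteins to their closest module.

    The q = 0.99 - 0.02*deep_split quantile rule is applied first to the
    whole tree and then recursively within each candidate branch: a branch
    whose own-subtree quantile cut yields two or more sub-branches of at
    least ``min_module_size`` is split.  TOM heights compress into a narrow
    band near 1, so a single global threshold can sit on the wrong side of a
    between-module merge; the per-branch re-cut resolves that, and any
    over-split of a genuine module is repaired downstream by eigenprotein
    merging.  Returns (linkage matrix, labels); label 0 = unassigned.
    """
    params.validate()
    ids = TOM.index
    if len(ids) < params.min_module_size:
        raise ValueError("fewer proteins than min_module_size")
    D = 1.0 - np.asarray(TOM, dtype=float)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")

    n = len(ids)
    children = Z[:, :2].astype(int)
    height = np.concatenate([np.zeros(n), Z[:, 2]])
    count = np.concatenate([np.ones(n, dtype=int), Z[:, 3].astype(int)])
    q = 0.99 - 0.02 * params.deep_split
    h0 = float(np.quantile(Z[:, 2], q))
    root = 2 * n - 2

    final_branches: list[list[int]] = []  # each: leaf index list
    work = [b for b in _cut_node(children, height, root, n, h0)]
    while work:
        b = work.pop()
        if count[b] < params.min_module_size:
            continue
        leaves, internal = _subtree_nodes(children, b, n)
        split = False
        if count[b] >= 2 * params.min_module_size and internal:
            hb = float(np.quantile(height[internal], q))
            if hb < height[b]:
                parts = _cut_node(children, height, b, n, hb)
                big = [p for p in parts if count[p] >= params.min_module_size]
                if len(big) >= 2:
                    work.extend(big)
                    split = True
        if not split:
            final_branches.append(leaves)

    labels = np.zeros(n, dtype=int)
    for next_id, leaves in enumerate(sorted(final_branches, key=min), start=1):
        labels[leaves] = next_id

    if params.pam_stage and labels.max() > 0:
        if params.pam_respects_dendro:
            allowed = _dendro_allowed_modules(Z, labels)
        else:
            all_mods = set(range(1, labels.max() + 1))
            allowed = [all_mods for _ in range(len(ids))]
        unassigned = np.where(labels == 0)[0]
        module_members = {m: np.where(labels == m)[0]
                          for m in range(1, labels.max() + 1)}
        new_labels = labels.copy()
        for o in unassigned:
            cand = allowed[o] or set(module_members)
            d_best, m_best = np.inf, 0
            for m in sorted(cand):
                d = D[o, module_members[m]].mean()
                if d < d_best:
                    d_best, m_best = d, m
            pool = unassigned[unassigned != o]
            d_pool = D[o, pool].mean() if len(pool) else np.inf
            if m_best and d_best < d_pool:
                new_labels[o] = m_best
        labels = new_labels

    labels = renumber_by_size(pd.Series(labels, index=ids, name="module"))
    return Z, labels


def renumber_by_size(labels: pd.Series) -> pd.Series:
    """Relabel modules 1..K by nonincreasing size (ties: smaller original
    label first); 0 stays unassigned."""
    counts = labels[labels > 0].value_counts()
    order = sorted(counts.index, key=lambda m: (-counts[m], m))
    mapping = {old: new for new, old in enumerate(order, start=1)}
    mapping[0] = 0
    return labels.map(mapping).astype(int)


# ---------------------------------------------------------------------------
# eigenproteins and kME

def _zscore_impute(vals: np.ndarray) -> np.ndarray:
    """Row z-scores with per-protein mean imputation (decomposition only)."""
    mean = np.nanmean(vals, axis=1, keepdims=True)
    sd = np.nanstd(vals, axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (vals - mean) / sd
    return np.where(np.isfinite(z), z, 0.0)


def module_eigenproteins(X: AbundanceMatrix, labels: pd.Series
                         ) -> tuple[pd.DataFrame, pd.Series]:
    """First principal component of each module's standardised profiles.

    Each member protein is z-scored across samples (missing values imputed
    with the protein mean for the decomposition only); the eigenprotein is
    the leading right-singular vector scaled to unit variance, oriented so
    its bicor with the module's mean z-profile is nonnegative.  Returns
    (modules x samples ME matrix, per-module variance explained).
    """
    vals = X.values.to_numpy(dtype=float)
    mods = sorted(m for m in labels.unique() if m > 0)
    mes, ve = {}, {}
    for m in mods:
        rows = np.where(labels.to_numpy() == m)[0]
        if len(rows) < 2:
            raise ValueError(f"module {m} has fewer than 2 members")
        Zm = _zscore_impute(vals[rows])
        U, s, Vt = np.linalg.svd(Zm, full_matrices=False)
        me = Vt[0]
        sd = me.std(ddof=1)
        me = me / (sd if sd > 0 else 1.0)
        ref = Zm.mean(axis=0)
        r = bicor(me, ref)
        if (np.isfinite(r) and r < 0) or (not np.isfinite(r) and me.sum() < 0):
            me = -me
        mes[f"M{m}"] = me
        tot = float((s ** 2).sum())
        ve[f"M{m}"] = float(s[0] ** 2 / tot) if tot > 0 else 0.0
    ME = pd.DataFrame(mes, index=X.sample_ids).T
    return ME, pd.Series(ve, name="var_explained")


def kme_table(X: AbundanceMatrix, ME: pd.DataFrame) -> pd.DataFrame:
    """kME_gm = bicor(protein g, eigenprotein m) for every protein (greys
    included) and module."""
    K = bicor_between(X.values, ME)
    return pd.DataFrame(K, index=X.protein_ids, columns=ME.index)


# ---------------------------------------------------------------------------
# module refinement

def _one_reassign_sweep(kme: pd.DataFrame, labels: pd.Series,
                        gap: float, floor: float) -> pd.Series:
    """Apply the three kME rules once (module columns named 'M<id>')."""
    kv = kme.to_numpy()
    mod_ids = np.array([int(c[1:]) for c in kme.columns])
    new = labels.copy()
    with np.errstate(invalid="ignore"):
        best = np.nanargmax(np.where(np.isfinite(kv), kv, -np.inf), axis=1)
    maxk = kv[np.arange(len(kv)), best]
    for i, g in enumerate(labels.index):
        cur = labels.iloc[i]
        if not np.isfinite(maxk[i]):
            continue
        if maxk[i] < floor:                       # R3: all kMEs below floor
            new.iloc[i] = 0
        elif cur == 0:                            # R2: assignable grey
            new.iloc[i] = mod_ids[best[i]]
        else:                                     # R1: gap rule
            col = np.where(mod_ids == cur)[0]
            k_cur = kv[i, col[0]] if len(col) else -np.inf
            if not np.isfinite(k_cur) or k_cur < maxk[i] - gap:
                new.iloc[i] = mod_ids[best[i]]
    return new


def reassign_members(X: AbundanceMatrix, labels: pd.Series,
                     params: NetworkParams
                     ) -> tuple[pd.Series, int, bool]:
    """Iteratively enforce the three kME membership rules: (R1) a protein's
    kME to its own module must lie within ``reassign_kme_gap`` of its best
    kME, (R2) a grey protein with any kME above ``kme_assign_floor`` is
    assigned to its best module, (R3) a protein whose kMEs are all below the
    floor goes grey.  Eigenproteins and kMEs are recomputed after every
    sweep; returns (labels, sweeps used, converged)."""
    labels = labels.copy()
    converged = False
    it = 0
    for it in range(1, params.max_reassign_iterations + 1):
        labels = _dissolve_tiny(labels)
        if (labels > 0).sum() == 0:
            converged = True
            break
        ME, _ = module_eigenproteins(X, labels)
        kme = kme_table(X, ME)
        new = _one_reassign_sweep(kme, labels, params.reassign_kme_gap,
                                  params.kme_assign_floor)
        if new.equals(labels):
            converged = True
            break
        labels = new
    if not converged:
        log.warning("reassign_members: not converged after %d sweeps", it)
    return labels, it, converged


def _dissolve_tiny(labels: pd.Series, min_size: int = 2) -> pd.Series:
    counts = labels[labels > 0].value_counts()
    tiny = counts.index[counts < min_size]
    if len(tiny):
        labels = labels.where(~labels.isin(tiny), 0)
    return labels


def audit_reassignment(kme: pd.DataFrame, labels: pd.Series,
                       params: NetworkParams) -> bool:
    """True iff the labels are a fixed point of the three kME rules."""
    new = _one_reassign_sweep(kme, labels, params.reassign_kme_gap,
                              params.kme_assign_floor)
    return bool(new.equals(labels))


def merge_close_modules(X: AbundanceMatrix, labels: pd.Series,
                        cut_height: float = 0.07) -> pd.Series:
    """Merge modules whose eigenproteins cluster below ``cut_height`` on the
    dissimilarity 1 - cor(ME_i, ME_j) (average linkage); eigenproteins are
    recomputed and merging repeated until stable."""
    labels = labels.copy()
    while True:
        mods = sorted(m for m in labels.unique() if m > 0)
        if len(mods) < 2:
            return labels
        ME, _ = module_eigenproteins(X, labels)
        corr = np.corrcoef(ME.to_numpy())
        D = np.clip(1.0 - corr, 0.0, None)
        np.fill_diagonal(D, 0.0)
        Z = linkage(squareform(D, checks=False), method="average")
        groups = fcluster(Z, t=cut_height, criterion="distance")
        if len(np.unique(groups)) == len(mods):
            return labels
        for grp in np.unique(groups):
            members = [mods[i] for i in np.where(groups == grp)[0]]
            if len(members) > 1:
                target = min(members)
                labels = labels.where(~labels.isin(members), target)


# ---------------------------------------------------------------------------
# end-to-end construction

def build_network(X: AbundanceMatrix, params: NetworkParams | None = None
                  ) -> NetworkModel:
    """Full chain: bicor -> signed adjacency -> TOM -> module detection ->
    merge of correlated modules -> iterative kME reassignment -> renumber by
    size -> final eigenproteins / kME."""
    params = params or NetworkParams()
    params.validate()
    C = bicor_matrix(X)
    A = signed_adjacency(C, params.soft_power)
    T = tom_similarity(A, params.tom_denom)
    Z, labels = detect_modules(T, params)
    labels = merge_close_modules(X, labels, params.merge_cut_height)
    labels, n_iter, converged = reassign_members(X, labels, params)
    labels = renumber_by_size(labels)
    ME, ve = module_eigenproteins(X, labels)
    kme = kme_table(X, ME)
    log.info("build_network: %d modules, %d grey, reassignment %s in %d sweeps",
             int((labels.value_counts().index > 0).sum()),
             int((labels == 0).sum()),
             "converged" if converged else "NOT converged", n_iter)
    return NetworkModel(correlation=C, adjacency=A, tom=T, dendrogram=Z,
                        labels=labels, eigenproteins=ME, var_explained=ve,
                        kme=kme, params=params, reassign_iterations=n_iter,
                        reassign_converged=converged)
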