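"""Weighted coexpression network core.

Implements the usual WGCNA-style stack on a log-expression matrix:
connectivity-based sample outlier removal, scale-free soft-threshold
selection, (un)signed adjacency, topological overlap, average-linkage
module detection with a static height cut, module eigengenes by SVD,
module membership (kME), eigengene-correlation module merging, hub-gene
extraction, and a one-way ANOVA with Tukey-Kramer post-hoc contrasts on
eigengene values across experimental groups.

Modules are labeled M1, M2, ... in decreasing size order (ties broken by
the lexicographically smallest member gene); genes in clusters below the
minimum size carry the reserved label "unassigned".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

UNASSIGNED = "unassigned"


@dataclass
class NetworkParams:
    power: int = 6
    network_type: str = "unsigned"      # or "signed"
    scale_free_r2_target: float = 0.8
    cut_height: float = 0.99
    min_module_size: int = 30
    merge_r_threshold: float = 0.85
    hub_kme_threshold: float = 0.8

    def __post_init__(self):
        if self.power < 1:
            raise ValueError("power must be a positive integer")
        if self.network_type not in ("unsigned", "signed"):
            raise ValueError("network_type must be 'unsigned' or 'signed'")
        if not (0.0 < self.cut_height < 1.0):
            raise ValueError("cut_height must lie in (0, 1)")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")
        if not (0.0 < self.merge_r_threshold <= 1.0):
            raise ValueError("merge_r_threshold must lie in (0, 1]")


def _corr_genes(expr: pd.DataFrame) -> np.ndarray:
    vals = expr.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    if (sd == 0).any():
        bad = expr.index[sd == 0][0]
        raise ValueError(f"constant gene {bad!r} has undefined correlation")
    c = np.corrcoef(vals)
    return np.clip(c, -1.0, 1.0)


def remove_outlier_samples(expr: pd.DataFrame, zk_cutoff: float = -2.0
                           ) -> tuple[list[str], pd.Series]:
    """Single-pass connectivity outlier removal.

    Sample adjacency is (1 + cor) / 2 off-diagonal; connectivity k is its
    row sum; Z.K standardizes k; samples with Z.K < cutoff are dropped.
    A degenerate run where every sample has the same connectivity (sd = 0)
    keeps everything.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    vals = expr.to_numpy(dtype=float)
    sd = vals.std(axis=0)
    if (sd == 0).any():
        bad = expr.columns[sd == 0][0]
        raise ValueError(f"sample {bad!r} has a constant expression profile")
    cor = np.corrcoef(vals.T)
    adj = (1.0 + cor) / 2.0
    np.fill_diagonal(adj, 0.0)
    k = adj.sum(axis=1)
    k_sd = k.std(ddof=1)
    if k_sd == 0:
        zk = np.zeros_like(k)
    else:
        zk = (k - k.mean()) / k_sd
    zk_series = pd.Series(zk, index=expr.columns, name="Z.K")
    kept = [s for s, z in zk_series.items() if z >= zk_cutoff]
    return kept, zk_series


def adjacency(expr: pd.DataFrame, params: NetworkParams) -> pd.DataFrame:
    """Soft-thresholded coexpression adjacency with unit diagonal."""
    cor = _corr_genes(expr)
    if params.network_type == "unsigned":
        a = np.abs(cor) ** params.power
    else:
        a = ((1.0 + cor) / 2.0) ** params.power
    np.fill_diagonal(a, 1.0)
    a = np.clip((a + a.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


@dataclass
class SoftPowerReport:
    chosen: int
    fits: pd.DataFrame       # power, r2, slope
    warning: bool = False


def pick_soft_power(expr: pd.DataFrame,
                    candidate_powers: tuple[int, ...] = tuple(range(1, 21)),
                    params: NetworkParams | None = None,
                    n_bins: int = 10) -> SoftPowerReport:
    """Smallest power whose connectivity distribution looks scale-free.

    For each candidate, the scale-free fit index is the squared Pearson
    correlation of log10 p(k) against log10 k over connectivity bins,
    counted only when the slope is negative; the chosen power is the
    smallest one reaching the target R^2, else the largest candidate with
    a warning flag.
    """
    if expr.shape[0] < 20:
        raise ValueError("need at least 20 genes to assess scale-free fit")
    params = params or NetworkParams()
    cor = _corr_genes(expr)
    rows = []
    chosen = None
    for p in candidate_powers:
        if params.network_type == "unsigned":
            a = np.abs(cor) ** p
        else:
            a = ((1.0 + cor) / 2.0) ** p
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
        which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
        freqs, centers = [], []
        for b in range(n_bins):
            mask = which == b
            if mask.any():
                freqs.append(mask.mean())
                centers.append(k[mask].mean())
        if len(freqs) < 3:
            raise ValueError("fewer than 3 nonempty connectivity bins")
        logk = np.log10(np.maximum(centers, 1e-12))
        logp = np.log10(freqs)
        if np.std(logk) == 0 or np.std(logp) == 0:
            r2, slope = 0.0, 0.0
        else:
            slope, _, r, _, _ = stats.linregress(logk, logp)
            r2 = r ** 2 if slope < 0 else 0.0
        rows.append({"power": p, "r2": r2, "slope": slope})
        if chosen is None and r2 >= params.scale_free_r2_target:
            chosen = p
    fits = pd.DataFrame(rows)
    warning = chosen is None
    if chosen is None:
        chosen = max(candidate_powers)
    return SoftPowerReport(chosen, fits, warning)


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap: shared-neighbor-weighted adjacency similarity.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with k_i the connectivity excluding the diagonal; the diagonal is 1.
    """
    a = adj.to_numpy(dtype=float)
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if (a < -1e-12).any() or (a > 1 + 1e-12).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=1) - np.diag(a)
    shared = a @ a
    # drop the u = i and u = j terms (a_ii a_ij and a_ij a_jj) before adding a_ij back
    numer = shared - a * (np.diag(a)[:, None] + np.diag(a)[None, :]) + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, numer / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def cut_modules(tom: pd.DataFrame, params: NetworkParams) -> pd.Series:
    """Average-linkage clustering on 1 - TOM with a static height cut."""
    if tom.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    if not (0.0 < params.cut_height < 1.0):
        raise ValueError("cut_height must lie in (0, 1)")
    dissim = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(dissim, checks=False)
    tree = linkage(condensed, method="average")
    raw = fcluster(tree, t=params.cut_height, criterion="distance")
    labels = pd.Series(raw, index=tom.index)
    clusters = []
    for cid, members in labels.groupby(labels).groups.items():
        genes = sorted(members)
        if len(genes) >= params.min_module_size:
            clusters.append((len(genes), min(genes), genes))
    clusters.sort(key=lambda t: (-t[0], t[1]))
    assignment = pd.Series(UNASSIGNED, index=tom.index, name="module")
    for rank, (_, _, genes) in enumerate(clusters, start=1):
        assignment.loc[genes] = f"M{rank}"
    return assignment


def _zscore_rows(vals: np.ndarray) -> np.ndarray:
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    if (sd == 0).any():
        raise ValueError("constant gene inside module")
    return (vals - mu) / sd


def module_eigengene(expr: pd.DataFrame, assignment: pd.Series,
                     module: str) -> tuple[pd.Series, float]:
    """First singular vector over samples of the z-scored module block.

    The sign is oriented so that the mean correlation of module genes with
    the eigengene is nonnegative. Returns (unit-norm ME, variance explained).
    """
    genes = assignment.index[assignment == module]
    if len(genes) == 0:
        raise ValueError(f"module {module!r} is empty")
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    z = _zscore_rows(expr.loc[genes].to_numpy(dtype=float))
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    me = vt[0]
    var_explained = float(s[0] ** 2 / (s ** 2).sum())
    cors = z @ me / (np.linalg.norm(z, axis=1) * np.linalg.norm(me))
    if cors.mean() < 0:
        me = -me
    return pd.Series(me, index=expr.columns, name=module), var_explained


def eigengene_matrix(expr: pd.DataFrame, assignment: pd.Series) -> pd.DataFrame:
    """Module x sample matrix of eigengenes for every non-reserved module."""
    modules = sorted(m for m in assignment.unique() if m != UNASSIGNED)
    rows = {}
    for m in modules:
        me, _ = module_eigengene(expr, assignment, m)
        rows[m] = me
    return pd.DataFrame(rows).T


def kme(expr: pd.DataFrame, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of every gene with every module eigengene."""
    if list(expr.columns) != list(eigengenes.columns):
        eigengenes = eigengenes[expr.columns]
    vals = expr.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    if (sd == 0).any():
        bad = expr.index[sd == 0][0]
        raise ValueError(f"constant gene {bad!r}")
    zg = (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]
    mes = eigengenes.to_numpy(dtype=float)
    zm = ((mes - mes.mean(axis=1, keepdims=True))
          / mes.std(axis=1, keepdims=True))
    n = vals.shape[1]
    table = np.clip(zg @ zm.T / n, -1.0, 1.0)
    return pd.DataFrame(table, index=expr.index, columns=eigengenes.index)


def merge_modules(expr: pd.DataFrame, assignment: pd.Series,
                  params: NetworkParams) -> pd.Series:
    """Iteratively merge the most correlated eigengene pair while R > cutoff.

    Strictly greater than the threshold; after each merge the eigengenes
    are recomputed. The merged module keeps the alphabetically first label;
    ties in correlation break on the (sorted) label pair.
    """
    assignment = assignment.copy()
    while True:
        modules = sorted(m for m in assignment.unique() if m != UNASSIGNED)
        if len(modules) < 2:
            break
        mes = eigengene_matrix(expr, assignment)
        cor = np.corrcoef(mes.to_numpy(dtype=float))
        best = None
        for i in range(len(modules)):
            for j in range(i + 1, len(modules)):
                r = cor[i, j]
                if best is None or r > best[0] + 1e-15:
                    best = (r, modules[i], modules[j])
        r, keep, absorb = best
        if not (r > params.merge_r_threshold):
            break
        assignment[assignment == absorb] = keep
    return assignment


def hub_genes(kme_table: pd.DataFrame, assignment: pd.Series, module: str,
              params: NetworkParams) -> list[str]:
    """Module members with kME at or above the hub threshold, best first."""
    if module not in set(assignment):
        raise ValueError(f"unknown module {module!r}")
    genes = assignment.index[assignment == module]
    vals = kme_table.loc[genes, module]
    hubs = vals[vals >= params.hub_kme_threshold]
    return list(hubs.sort_values(ascending=False, kind="stable").index)


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame      # group_a, group_b, p_adj
    degenerate: bool = False


def eigengene_anova(eigengenes: pd.DataFrame | pd.Series, meta: pd.DataFrame,
                    module: str, grouping: str) -> AnovaResult:
    """One-way ANOVA plus Tukey-Kramer pairwise comparisons on ME values."""
    me = eigengenes.loc[module] if isinstance(eigengenes, pd.DataFrame) \
        else eigengenes
    groups = meta.loc[me.index, grouping]
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [me[groups == lv].to_numpy(dtype=float) for lv in levels]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")
    within_var = sum(a.var(ddof=1) for a in arrays)
    means = [a.mean() for a in arrays]
    if within_var == 0 and np.ptp(means) == 0:
        pairs = [(a, b, 1.0) for i, a in enumerate(levels)
                 for b in levels[i + 1:]]
        tukey = pd.DataFrame(pairs, columns=["group_a", "group_b", "p_adj"])
        return AnovaResult(0.0, 1.0, tukey, degenerate=True)
    f, p = stats.f_oneway(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    pairs = []
    for i, a in enumerate(levels):
        for j, b in enumerate(levels):
            if j <= i:
                continue
            pairs.append((a, b, float(hsd.pvalue[i, j])))
    tukey = pd.DataFrame(pairs, columns=["group_a", "group_b", "p_adj"])
    return AnovaResult(float(f), float(p), tukey)
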