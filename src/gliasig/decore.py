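"""Negative-binomial differential expression on bulk count matrices.

The model is the standard RNA-seq workhorse: per-sample size factors by
median-of-ratios, per-gene NB dispersion alpha (Var = mu + alpha mu^2) by
method of moments within replicated design cells, and a per-gene NB
generalized linear model with log link and log size-factor offset, fit by
iteratively reweighted least squares at fixed alpha. Contrasts are tested
with a Wald statistic on the log2 fold change; p-values are adjusted by
Benjamini-Hochberg. Batch is handled as a categorical covariate in the
regression rather than by a separate removal step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

LN2 = float(np.log(2.0))
ALPHA_FLOOR = 1e-8


def _validate_counts(counts: pd.DataFrame) -> None:
    if counts.index.duplicated().any():
        raise ValueError("duplicate gene ids")
    if counts.columns.duplicated().any():
        raise ValueError("duplicate sample ids")
    vals = counts.to_numpy()
    if np.isnan(vals).any():
        raise ValueError("count matrix contains missing values")
    if (vals < 0).any():
        raise ValueError("counts must be nonnegative")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalizers against a geometric-mean reference.

    Only genes with all-positive counts contribute; a single-sample matrix
    gets size factor 1.
    """
    _validate_counts(counts)
    if counts.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns)
    vals = counts.to_numpy(dtype=float)
    all_pos = (vals > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene has all-positive counts; the pseudo-reference "
            "fallback is disabled — filter samples or genes first")
    logc = np.log(vals[all_pos])
    log_ref = logc.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logc - log_ref, axis=0))
    return pd.Series(sf, index=counts.columns)


def estimate_dispersion(counts: pd.DataFrame, sf: pd.Series,
                        design: pd.Series) -> pd.Series:
    """Method-of-moments dispersion per gene, maximized over design cells.

    Within each design cell with >= 2 replicates, alpha = (s^2 - mu) / mu^2
    on size-factor-normalized counts; the per-gene estimate is the max over
    cells, floored at 1e-8. Genes with zero mean everywhere get the floor.
    """
    _validate_counts(counts)
    norm = counts.to_numpy(dtype=float) / sf.loc[counts.columns].to_numpy()
    groups = pd.Series(design, index=counts.columns)
    replicated = [g for g, idx in groups.groupby(groups).groups.items()
                  if len(idx) >= 2]
    if not replicated:
        raise ValueError("no design cell has >= 2 replicates")
    alpha = np.full(counts.shape[0], ALPHA_FLOOR)
    for g in replicated:
        cols = groups.index.get_indexer(groups.index[groups == g])
        sub = norm[:, cols]
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(mu > 0, (s2 - mu) / mu ** 2, ALPHA_FLOOR)
        alpha = np.maximum(alpha, a)
    return pd.Series(np.maximum(alpha, ALPHA_FLOOR), index=counts.index)


@dataclass
class ContrastResult:
    """Per-gene Wald-test results for one named contrast."""

    table: pd.DataFrame  # baseMean, log2FC, SE, waldZ, pvalue, padj
    name: str = ""

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


def _irls_nb(y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: float,
             max_iter: int = 100, tol: float = 1e-8):
    """Fit an NB log-link GLM at fixed alpha; return (beta, cov) or None.

    IRLS with working weights w = mu / (1 + alpha mu); the covariance is
    the inverse Fisher information at convergence.
    """
    n, p = X.shape
    beta = np.linalg.lstsq(X, np.log(y + 0.5) - offset, rcond=None)[0]
    for _ in range(max_iter):
        eta = X @ beta + offset
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        XtW = X.T * w
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(beta_new)):
            return None
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    else:
        return None
    eta = np.clip(X @ beta + offset, -30.0, 30.0)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha * mu)
    XtW = X.T * w
    try:
        cov = np.linalg.inv(XtW @ X)
    except np.linalg.LinAlgError:
        return None
    return beta, cov


def _design_matrix(meta: pd.DataFrame, factor: str, reference: str,
                   covariates: tuple[str, ...]):
    """Intercept + treatment-coded factor (given reference) + covariates."""
    levels = [l for l in pd.unique(meta[factor]) if l != reference]
    cols = [np.ones(len(meta))]
    names = ["intercept"]
    for lv in levels:
        cols.append((meta[factor] == lv).to_numpy(dtype=float))
        names.append(f"{factor}[{lv}]")
    for cov in covariates:
        cov_levels = sorted(pd.unique(meta[cov]))[1:]
        for lv in cov_levels:
            cols.append((meta[cov] == lv).to_numpy(dtype=float))
            names.append(f"{cov}[{lv}]")
    X = np.column_stack(cols)
    return X, names


def nb_wald_test(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    contrast: tuple[str, str, str],
    covariates: tuple[str, ...] = (),
    alpha: pd.Series | None = None,
    sf: pd.Series | None = None,
    min_mean_count: float = 0.0,
    name: str | None = None,
) -> ContrastResult:
    """Wald test of ``level_num`` vs ``level_den`` on ``factor``.

    Positive log2FC means higher expression in the numerator level. The
    model is fit on the samples belonging to the two contrast levels (a
    pairwise comparison); size factors may come from the full dataset.
    Genes that fail to converge (or are all-zero) are flagged with NA
    p-values and excluded from the BH denominator.
    """
    _validate_counts(counts)
    factor, num, den = contrast
    if factor not in meta.columns:
        raise ValueError(f"unknown factor {factor!r}")
    present = set(meta[factor])
    for lv in (num, den):
        if lv not in present:
            raise ValueError(f"contrast level {lv!r} absent from metadata")
    if list(meta.index) != list(counts.columns):
        meta = meta.loc[counts.columns]
    in_contrast = meta[factor].isin([num, den])
    meta = meta.loc[in_contrast]
    counts = counts.loc[:, meta.index]
    if sf is not None:
        sf = sf.loc[meta.index]

    if sf is None:
        sf = size_factors(counts)
    if alpha is None:
        groups = meta[factor].astype(str)
        for cov in covariates:
            groups = groups + "/" + meta[cov].astype(str)
        alpha = estimate_dispersion(counts, sf, groups)

    X, names = _design_matrix(meta, factor, den, covariates)
    c = np.zeros(X.shape[1])
    c[names.index(f"{factor}[{num}]")] = 1.0

    offset = np.log(sf.loc[counts.columns].to_numpy())
    norm = counts.to_numpy(dtype=float) / np.exp(offset)
    base_mean = norm.mean(axis=1)

    n_genes = counts.shape[0]
    log2fc = np.full(n_genes, np.nan)
    se = np.full(n_genes, np.nan)
    for i in range(n_genes):
        y = counts.iloc[i].to_numpy(dtype=float)
        if base_mean[i] < min_mean_count or y.sum() == 0:
            continue
        fit = _irls_nb(y, X, offset, float(alpha.iloc[i]))
        if fit is None:
            continue
        beta, cov = fit
        est = float(c @ beta)
        var = float(c @ cov @ c)
        if var <= 0 or not np.isfinite(var):
            continue
        log2fc[i] = est / LN2
        se[i] = np.sqrt(var) / LN2

    with np.errstate(invalid="ignore", divide="ignore"):
        wald = log2fc / se
    pvals = 2.0 * stats.norm.sf(np.abs(wald))
    padj = bh_adjust(pd.Series(pvals, index=counts.index))
    table = pd.DataFrame({
        "baseMean": base_mean, "log2FC": log2fc, "SE": se, "waldZ": wald,
        "pvalue": pvals, "padj": padj.to_numpy(),
    }, index=counts.index)
    return ContrastResult(table, name or f"{num}_vs_{den}")


def bh_adjust(pvalues: pd.Series | np.ndarray) -> pd.Series:
    """Benjamini-Hochberg step-up; NAs are ignored and returned as NA."""
    p = pd.Series(pvalues, dtype=float)
    valid = p.notna()
    vals = p[valid].to_numpy()
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    adj = np.full(len(p), np.nan)
    m = valid.sum()
    if m:
        order = np.argsort(vals, kind="stable")
        ranked = vals[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.clip(ranked, 0.0, 1.0)
        adj[valid.to_numpy()] = out
    return pd.Series(adj, index=p.index)


def shifted_log_transform(counts: pd.DataFrame, sf: pd.Series,
                          pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(count / size_factor + pseudocount), the network-input transform."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if (sf.loc[counts.columns] <= 0).any():
        raise ValueError("size factors must be positive")
    norm = counts.to_numpy(dtype=float) / sf.loc[counts.columns].to_numpy()
    return pd.DataFrame(np.log2(norm + pseudocount),
                        index=counts.index, columns=counts.columns)


def center_batches(expr: pd.DataFrame, batch: pd.Series) -> pd.DataFrame:
    """Per-batch gene-wise mean centering in log space (network input)."""
    out = expr.copy()
    grand = expr.mean(axis=1)
    for b in pd.unique(batch):
        cols = batch.index[batch == b]
        out.loc[:, cols] = (expr[cols].sub(expr[cols].mean(axis=1), axis=0)
                            .add(grand, axis=0))
    return out
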