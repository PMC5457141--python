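"""Cross-species harmonization and comparison of expression datasets.

Two species' count matrices are joined over single-copy (one-to-one)
orthologs, excluding rRNA- and mitochondria-flagged genes whose capture
efficiency differs across library protocols. Differential expression
between species reuses the NB Wald machinery with batch as a covariate;
global comparability is summarized by the Spearman rank correlation of
mean expression, and curated marker panels are reported as fractions
up / down / unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import decore
from .decore import ContrastResult
from .synthdata import OrthologMap


@dataclass
class HarmonizedPair:
    counts_a: pd.DataFrame
    counts_b: pd.DataFrame
    dropped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.counts_a.shape[0] != self.counts_b.shape[0]:
            raise ValueError("harmonized matrices must have equal gene counts")


def harmonize_orthologs(counts_a: pd.DataFrame, counts_b: pd.DataFrame,
                        omap: OrthologMap) -> HarmonizedPair:
    """Restrict both matrices to clean one-to-one orthologs.

    Keeps only records with homology_type one2one and biotype 'other';
    records whose genes are missing from either matrix are dropped with a
    tally. Gene ids in the output use the species-A id.
    """
    rec = omap.records
    if rec.duplicated(["idA", "idB"]).any():
        raise ValueError("duplicate (idA, idB) pairs in ortholog map")
    dropped = {"not_single_copy": 0, "rRNA": 0, "mito": 0, "missing": 0}
    multi_a = rec["idA"].duplicated(keep=False)
    multi_b = rec["idB"].duplicated(keep=False)
    keep_rows = []
    for i, row in rec.iterrows():
        if row["homology_type"] != "one2one" or multi_a[i] or multi_b[i]:
            dropped["not_single_copy"] += 1
        elif row["biotype"] in ("rRNA", "mito"):
            dropped[row["biotype"]] += 1
        elif row["idA"] not in counts_a.index or row["idB"] not in counts_b.index:
            dropped["missing"] += 1
        else:
            keep_rows.append((row["idA"], row["idB"]))
    if not keep_rows:
        raise ValueError("no usable orthologs after filtering")
    keep_rows.sort()
    ids_a = [a for a, _ in keep_rows]
    ids_b = [b for _, b in keep_rows]
    sub_a = counts_a.loc[ids_a]
    sub_b = counts_b.loc[ids_b]
    sub_b.index = ids_a
    dropped["kept"] = len(keep_rows)
    return HarmonizedPair(sub_a, sub_b, dropped)


def species_de(pair: HarmonizedPair,
               batch_labels: pd.Series | None = None,
               padj_threshold: float = 0.05) -> ContrastResult:
    """NB Wald test of species A vs species B on the harmonized universe."""
    if pair.counts_a.shape[1] < 2 or pair.counts_b.shape[1] < 2:
        raise ValueError("need at least 2 samples per species")
    counts = pd.concat([pair.counts_a, pair.counts_b], axis=1)
    if counts.columns.duplicated().any():
        counts.columns = ([f"A_{c}" for c in pair.counts_a.columns]
                          + [f"B_{c}" for c in pair.counts_b.columns])
    species = ["A"] * pair.counts_a.shape[1] + ["B"] * pair.counts_b.shape[1]
    meta = pd.DataFrame({"species": species}, index=counts.columns)
    covariates: tuple[str, ...] = ()
    if batch_labels is not None:
        meta["batch"] = batch_labels.to_numpy()
        if meta.groupby("batch")["species"].nunique().max() > 1:
            covariates = ("batch",)
    return decore.nb_wald_test(counts, meta, ("species", "A", "B"),
                               covariates=covariates, name="speciesA_vs_speciesB")


def de_fractions(contrast: ContrastResult,
                 padj_threshold: float = 0.05) -> dict[str, float]:
    tab = contrast.table
    sig = tab["padj"] < padj_threshold
    n = len(tab)
    return {
        "up": float((sig & (tab["log2FC"] > 0)).sum() / n),
        "down": float((sig & (tab["log2FC"] < 0)).sum() / n),
        "unchanged": float((~(sig.fillna(False))).sum() / n),
    }


def rank_correlation(mean_a: pd.Series, mean_b: pd.Series
                     ) -> tuple[float, float]:
    """Spearman rank correlation (average ranks on ties, t-approximation p)."""
    if len(mean_a) != len(mean_b):
        raise ValueError("vectors must have equal length")
    if len(mean_a) < 3:
        raise ValueError("need at least 3 values")
    if mean_a.nunique() == 1 or mean_b.nunique() == 1:
        raise ValueError("constant vector has undefined rank correlation")
    rho, p = stats.spearmanr(mean_a.to_numpy(), mean_b.to_numpy())
    return float(rho), float(p)


def species_mean_expression(pair: HarmonizedPair) -> tuple[pd.Series, pd.Series]:
    """Shifted-log normalized per-species mean expression (for rank cor)."""
    means = []
    for counts in (pair.counts_a, pair.counts_b):
        sf = decore.size_factors(counts)
        expr = decore.shifted_log_transform(counts, sf)
        means.append(expr.mean(axis=1))
    return means[0], means[1]


def marker_panel_report(contrast: ContrastResult, panel: set[str],
                        padj_threshold: float = 0.05
                        ) -> tuple[dict[str, float], pd.DataFrame]:
    """Fractions of a marker panel up / down / unchanged, plus a gene table."""
    present = sorted(set(panel) & set(contrast.table.index))
    missing = sorted(set(panel) - set(present))
    if not present:
        raise ValueError("panel does not intersect the contrast universe")
    tab = contrast.table.loc[present]
    sig = tab["padj"] < padj_threshold
    status = np.where(sig & (tab["log2FC"] > 0), "up",
                      np.where(sig & (tab["log2FC"] < 0), "down", "unchanged"))
    per_gene = tab.assign(status=status, missing=False)
    n = len(present)
    fractions = {
        "up": float((status == "up").sum() / n),
        "down": float((status == "down").sum() / n),
        "unchanged": float((status == "unchanged").sum() / n),
        "n_present": n, "n_missing": len(missing),
    }
    return fractions, per_gene
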