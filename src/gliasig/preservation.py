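"""Permutation Z-statistics for module preservation across two networks.

Given module assignments learned in a reference expression dataset, each
module is scored in a test dataset by two composite statistics: density
(mean intramodule adjacency in the test network) and connectivity
(agreement of intramodular connectivity patterns between reference and
test). A null distribution comes from reassigning the test network's
module labels to random genes of the same module size over the common
gene universe (the reference keeps the true membership); Z-scores
standardize the observed statistics against that null, and
Zsummary = (Zdensity + Zconnectivity) / 2. Interpretation bands follow
common practice: Zsummary < 2 is no evidence of preservation, > 10 is
strong preservation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .netcore import NetworkParams, UNASSIGNED, adjacency

INTERPRETATION_BANDS = {"not_significant": 2.0, "highly_significant": 10.0}


@dataclass
class PreservationReport:
    table: pd.DataFrame    # module, size, Zdensity, Zconnectivity, Zsummary, ...
    n_permutations: int

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["band_lo"] = INTERPRETATION_BANDS["not_significant"]
        out["band_hi"] = INTERPRETATION_BANDS["highly_significant"]
        out.to_csv(path, sep="\t", index=False)


def _module_stats(a_ref: np.ndarray, a_test: np.ndarray, idx_ref: np.ndarray,
                  idx_test: np.ndarray) -> tuple[float, float, float]:
    """(density, cor(kIM), cor(adjacency entries)) for one labeled gene set.

    Under the null the test-side labels are permuted, so ``idx_test`` is a
    random same-size draw while the reference keeps the true module genes.
    """
    sub_ref = a_ref[np.ix_(idx_ref, idx_ref)]
    sub_test = a_test[np.ix_(idx_test, idx_test)]
    m = len(idx_ref)
    off = ~np.eye(m, dtype=bool)
    density = float(sub_test[off].mean())
    k_ref = sub_ref.sum(axis=1) - 1.0
    k_test = sub_test.sum(axis=1) - 1.0
    cor_k = _safe_cor(k_ref, k_test)
    iu = np.triu_indices(m, k=1)
    cor_adj = _safe_cor(sub_ref[iu], sub_test[iu])
    return density, cor_k, cor_adj


def _safe_cor(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def module_preservation(
    expr_ref: pd.DataFrame,
    expr_test: pd.DataFrame,
    assignment: pd.Series,
    params: NetworkParams | None = None,
    n_perm: int = 200,
    seed: int = 0,
) -> PreservationReport:
    """Score each module's preservation in the test dataset.

    Both expression matrices are genes x samples; adjacency parameters are
    shared. Modules smaller than 3 genes (after intersecting with the
    common universe) are an error.
    """
    params = params or NetworkParams()
    if n_perm < 50:
        raise ValueError("n_perm must be at least 50")
    common = expr_ref.index.intersection(expr_test.index)
    if len(common) < 3:
        raise ValueError("fewer than 3 genes shared between datasets")
    modules = sorted(m for m in assignment.unique() if m != UNASSIGNED)
    members = {}
    for m in modules:
        genes = assignment.index[assignment == m].intersection(common)
        if len(genes) < 3:
            raise ValueError(f"module {m!r} has fewer than 3 genes in the "
                             "common universe")
        members[m] = genes

    a_ref = adjacency(expr_ref.loc[common], params).to_numpy()
    a_test = adjacency(expr_test.loc[common], params).to_numpy()
    pos = {g: i for i, g in enumerate(common)}

    rng = np.random.default_rng(seed)
    rows = []
    n_universe = len(common)
    for m in modules:
        idx = np.array([pos[g] for g in members[m]])
        obs = _module_stats(a_ref, a_test, idx, idx)
        null = np.empty((n_perm, 3))
        for p in range(n_perm):
            rand_idx = rng.choice(n_universe, size=len(idx), replace=False)
            null[p] = _module_stats(a_ref, a_test, idx, rand_idx)
        mean = null.mean(axis=0)
        sd = null.std(axis=0, ddof=1)
        sd[sd == 0] = np.nan
        z = (np.array(obs) - mean) / sd
        z_density = float(z[0])
        z_connectivity = float(np.median(z[1:3]))
        rows.append({
            "module": m, "size": len(idx),
            "density": obs[0], "cor_kIM": obs[1], "cor_adj": obs[2],
            "Zdensity": z_density, "Zconnectivity": z_connectivity,
            "Zsummary": (z_density + z_connectivity) / 2.0,
            "n_perm": n_perm,
        })
    return PreservationReport(pd.DataFrame(rows), n_perm)
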