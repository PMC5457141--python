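"""Shared fixtures: simulations reused across test modules.

The recovery benchmark (200 planted signature genes among 2200, the
three-genotype x three-stage x triplicate design) is expensive enough to
build once per session; downstream tests consume views of it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gliasig import decore, netcore, screen, synthdata

BENCHMARK_SEED = 11

DEFAULT_CONTRAST_SPECS = [
    ("WT_E13.5_vs_WT_E12.5", ("group", "WT_E13.5", "WT_E12.5")),
    ("WT_E14.5_vs_WT_E13.5", ("group", "WT_E14.5", "WT_E13.5")),
    ("cKO_E14.5_vs_WT_E14.5", ("group", "cKO_E14.5", "WT_E14.5")),
    ("rescue_E14.5_vs_WT_E14.5", ("group", "rescue_E14.5", "WT_E14.5")),
]


@pytest.fixture(scope="session")
def benchmark():
    """Simulated benchmark experiment plus its four standard contrasts."""
    cfg = synthdata.recovery_benchmark_config(seed=BENCHMARK_SEED)
    counts, meta, truth = synthdata.simulate_bulk_experiment(cfg)
    meta = meta.assign(group=screen.group_column(meta))
    contrasts = screen.run_contrast_set(counts, meta, DEFAULT_CONTRAST_SPECS)
    planted = {g for g, m in truth.module_membership.items()
               if m != "background"}
    return {"counts": counts, "meta": meta, "truth": truth,
            "contrasts": contrasts, "planted": planted}


@pytest.fixture(scope="session")
def benchmark_network(benchmark):
    """Coexpression network built on the benchmark expression matrix."""
    counts, meta = benchmark["counts"], benchmark["meta"]
    sf = decore.size_factors(counts)
    expr = decore.shifted_log_transform(counts, sf)
    kept, zk = netcore.remove_outlier_samples(expr)
    expr = expr[kept]
    params = netcore.NetworkParams()
    power = netcore.pick_soft_power(expr, params=params)
    params.power = power.chosen
    adj = netcore.adjacency(expr, params)
    tom = netcore.tom_similarity(adj)
    assignment = netcore.cut_modules(tom, params)
    assignment = netcore.merge_modules(expr, assignment, params)
    mes = netcore.eigengene_matrix(expr, assignment)
    kme_table = netcore.kme(expr, mes)
    return {"expr": expr, "params": params, "assignment": assignment,
            "eigengenes": mes, "kme": kme_table, "kept": kept, "zk": zk,
            "power_report": power, "meta": meta.loc[kept]}


@pytest.fixture(scope="session")
def single_cell_sim():
    """1000 cells (200 bRG carrying a 40-gene signature at 4-fold)."""
    genes = [f"g{i:05d}" for i in range(500)]
    signature = tuple(genes[:40])
    cfg = synthdata.SingleCellSimConfig(
        cell_types=[
            synthdata.CellTypeSpec("bRG", 200, signature, 2.0),
            synthdata.CellTypeSpec("aRG", 400),
            synthdata.CellTypeSpec("IPC", 400),
        ],
        n_genes=500, seed=3)
    matrix, labels = synthdata.simulate_single_cells(cfg)
    return {"matrix": matrix, "labels": labels, "signature": signature}


def nb_counts(rng: np.random.Generator, mu, alpha, size=None) -> np.ndarray:
    """Reference gamma-Poisson draw used by simulation oracles in tests."""
    lam = rng.gamma(1.0 / alpha, alpha * np.asarray(mu, dtype=float),
                    size=size)
    return rng.poisson(lam)
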