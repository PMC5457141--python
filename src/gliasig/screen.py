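"""Intersection-of-lists candidate screen over named DE contrasts.

Candidate genes for a perturbation-dependent cell type are defined by a
boolean rule over differential-expression atoms: up at some stage step in
wild type, down in the knockout, and back to normal (not significant) in
the rescue. The rule engine is generic: atoms reference named contrasts
and are combined with AND/OR/NOT expressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import decore
from .decore import ContrastResult

DIRECTIONS = ("up", "down", "not_significant")


@dataclass(frozen=True)
class Atom:
    """One thresholded condition on one contrast.

    up: padj < threshold and log2FC >= +min_abs_log2FC
    down: padj < threshold and log2FC <= -min_abs_log2FC
    not_significant: padj >= threshold
    A gene with NA padj fails every direction and is recorded as dropped.
    """

    contrast_name: str
    direction: str
    padj_threshold: float = 0.05
    min_abs_log2FC: float = 0.0

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if not (0.0 < self.padj_threshold <= 1.0):
            raise ValueError("padj_threshold must be in (0, 1]")


# Boolean expressions are nested lists: ["and", x, y], ["or", x, y],
# ["not", x], or an atom name (string).
Expression = str | list


@dataclass
class ScreenRules:
    atoms: Mapping[str, Atom]
    expression: Expression

    def referenced_contrasts(self) -> set[str]:
        return {a.contrast_name for a in self.atoms.values()}


def default_rules(padj_threshold: float = 0.05,
                  min_abs_log2FC: float = 0.0) -> ScreenRules:
    """The published screen logic: rising across WT stages (either step),
    down in the knockout at E14.5, and not significant in rescue vs WT."""
    atoms = {
        "up_e13_vs_e12": Atom("WT_E13.5_vs_WT_E12.5", "up",
                              padj_threshold, min_abs_log2FC),
        "up_e14_vs_e13": Atom("WT_E14.5_vs_WT_E13.5", "up",
                              padj_threshold, min_abs_log2FC),
        "down_cko": Atom("cKO_E14.5_vs_WT_E14.5", "down",
                         padj_threshold, min_abs_log2FC),
        "normal_rescue": Atom("rescue_E14.5_vs_WT_E14.5", "not_significant",
                              padj_threshold),
    }
    expression = ["and", ["or", "up_e13_vs_e12", "up_e14_vs_e13"],
                  "down_cko", "normal_rescue"]
    return ScreenRules(atoms, expression)


@dataclass
class CandidateSet:
    genes: list[str]
    audit: pd.DataFrame           # gene x atom truth table (plus "included")
    dropped_na: list[str] = field(default_factory=list)


def run_contrast_set(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    contrast_specs: Sequence[tuple[str, tuple[str, str, str]]],
    covariates: tuple[str, ...] = (),
    **kwargs,
) -> dict[str, ContrastResult]:
    """Compute a batch of named NB Wald contrasts on one dataset.

    ``contrast_specs`` is a sequence of (name, (factor, num, den)). Size
    factors and dispersions are shared across contrasts.
    """
    names = [n for n, _ in contrast_specs]
    if len(names) != len(set(names)):
        raise ValueError("duplicate contrast names")
    if not contrast_specs:
        return {}
    sf = decore.size_factors(counts)
    results: dict[str, ContrastResult] = {}
    for cname, contrast in contrast_specs:
        try:
            results[cname] = decore.nb_wald_test(
                counts, meta, contrast, covariates=covariates, sf=sf,
                name=cname, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"contrast {cname!r} failed: {exc}") from exc
    return results


def group_column(meta: pd.DataFrame,
                 cols: Sequence[str] = ("genotype", "stage")) -> pd.Series:
    """Combine metadata factors into a single design-cell factor."""
    combined = meta[cols[0]].astype(str)
    for c in cols[1:]:
        combined = combined + "_" + meta[c].astype(str)
    return combined


def _atom_truth(atom: Atom, result: ContrastResult) -> pd.Series:
    tab = result.table
    padj = tab["padj"]
    lfc = tab["log2FC"]
    if atom.direction == "up":
        truth = (padj < atom.padj_threshold) & (lfc >= atom.min_abs_log2FC)
    elif atom.direction == "down":
        truth = (padj < atom.padj_threshold) & (lfc <= -atom.min_abs_log2FC)
    else:
        truth = padj >= atom.padj_threshold
    return truth.fillna(False)


def _eval_expression(expr: Expression, truths: Mapping[str, pd.Series]) -> pd.Series:
    if isinstance(expr, str):
        if expr not in truths:
            raise ValueError(f"unknown atom {expr!r}")
        return truths[expr]
    op, *args = expr
    if op == "not":
        if len(args) != 1:
            raise ValueError("'not' takes exactly one argument")
        return ~_eval_expression(args[0], truths)
    parts = [_eval_expression(a, truths) for a in args]
    if not parts:
        raise ValueError(f"empty {op!r} expression")
    out = parts[0]
    for p in parts[1:]:
        out = (out & p) if op == "and" else (out | p)
    if op not in ("and", "or"):
        raise ValueError(f"unknown operator {op!r}")
    return out


def intersect_candidates(results: Mapping[str, ContrastResult],
                         rules: ScreenRules) -> CandidateSet:
    """Evaluate the boolean rule per gene over the contrast results."""
    for aname, atom in rules.atoms.items():
        if atom.contrast_name not in results:
            raise ValueError(
                f"atom {aname!r} references unknown contrast "
                f"{atom.contrast_name!r}")
    universe = None
    for res in results.values():
        idx = res.table.index
        universe = idx if universe is None else universe.intersection(idx)
    universe = universe if universe is not None else pd.Index([])

    truths: dict[str, pd.Series] = {}
    na_any = pd.Series(False, index=universe)
    for aname, atom in rules.atoms.items():
        res = results[atom.contrast_name]
        truths[aname] = _atom_truth(atom, res).reindex(universe)
        na_any |= res.table["padj"].reindex(universe).isna()

    included = _eval_expression(rules.expression, truths)
    included &= ~na_any  # genes untestable in any referenced contrast drop out

    audit = pd.DataFrame(truths, index=universe)
    audit["na_dropped"] = na_any
    audit["included"] = included
    return CandidateSet(genes=sorted(universe[included]),
                        audit=audit,
                        dropped_na=sorted(universe[na_any]))


def early_response_filter(timecourse: pd.DataFrame,
                          max_hr: float = 4.0,
                          min_log2fc: float = 1.0,
                          padj_threshold: float = 0.05) -> list[str]:
    """Genes up at least 2-fold (adjusted p < 0.05) within 4 hours.

    ``timecourse`` rows: gene, timepoint_hr, log2FC_vs_t0, padj.
    """
    required = {"gene", "timepoint_hr", "log2FC_vs_t0", "padj"}
    if not required.issubset(timecourse.columns):
        raise ValueError(f"timecourse table needs columns {sorted(required)}")
    tc = timecourse.copy()
    if (pd.to_numeric(tc["timepoint_hr"], errors="coerce") < 0).any() or \
            pd.to_numeric(tc["timepoint_hr"], errors="coerce").isna().any():
        raise ValueError("timepoints must be nonnegative numbers")
    hit = ((tc["timepoint_hr"] <= max_hr)
           & (tc["log2FC_vs_t0"] >= min_log2fc)
           & (tc["padj"] < padj_threshold))
    return sorted(tc.loc[hit, "gene"].unique())
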