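"""Synthetic data generators for the perturbation RNA-seq study design.

The generators emulate the statistical structure of a genetic-perturbation
bulk RNA-seq experiment in the embryonic cerebellum: a latent cell-type
abundance (nascent Bergmann glia) rises across developmental stages E12.5
to E14.5 in wild-type animals, is ablated in a conditional knockout, and
is restored in a rescue genotype. Genes belonging to planted coexpression
modules track that latent abundance on the log2 scale; everything else is
independent baseline noise. Counts are negative-binomial via the standard
gamma-Poisson mixture so that the moments match the downstream estimator:
Var = mu + alpha * mu^2.

Companion generators produce single-cell matrices with cell-type signature
genes (apical/basal radial glia and intermediate progenitors), paired
two-species bulk datasets sharing module structure through an ortholog map,
and blinded in-situ-hybridization scoring tables on the 0-3 rubric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

GENOTYPES = ("WT", "cKO", "rescue")
STAGES = ("E12.5", "E13.5", "E14.5")

#: latent basal-glia abundance per (genotype, stage): absent at E12.5,
#: rising through E14.5 in WT, flat zero in the knockout, restored in rescue
DEFAULT_ABUNDANCE: dict[tuple[str, str], float] = {
    ("WT", "E12.5"): 0.0, ("WT", "E13.5"): 0.5, ("WT", "E14.5"): 1.0,
    ("cKO", "E12.5"): 0.0, ("cKO", "E13.5"): 0.0, ("cKO", "E14.5"): 0.0,
    ("rescue", "E12.5"): 0.0, ("rescue", "E13.5"): 0.5, ("rescue", "E14.5"): 1.0,
}


@dataclass(frozen=True)
class PlantedModule:
    """A block of genes whose expression tracks the latent abundance.

    ``effect_profile`` optionally overrides the experiment-level abundance
    mapping for this module ((genotype, stage) -> abundance in [0, 1]).
    """

    name: str
    size: int
    effect_profile: Mapping[tuple[str, str], float] | None = None


@dataclass(frozen=True)
class DesignCell:
    genotype: str
    stage: str
    n_replicates: int = 3
    batch: str = "b1"


def default_design(n_replicates: int = 3) -> list[DesignCell]:
    """Three genotypes x three stages x ``n_replicates``, one batch."""
    return [DesignCell(g, s, n_replicates)
            for g in GENOTYPES for s in STAGES]


@dataclass
class BulkSimConfig:
    n_genes: int = 2000
    planted_modules: list[PlantedModule] = field(
        default_factory=lambda: [PlantedModule("BG", 150)])
    design: list[DesignCell] = field(default_factory=default_design)
    abundance: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_ABUNDANCE))
    effect_size_log2: float = 2.0
    baseline_log2_mean_range: tuple[float, float] = (3.0, 10.0)
    dispersion_range: tuple[float, float] = (0.005, 0.05)
    libsize_range: tuple[float, float] = (0.75, 1.33)
    batch_sd_log2: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be nonnegative")
        if sum(m.size for m in self.planted_modules) > self.n_genes:
            raise ValueError("planted module sizes exceed n_genes")
        if not self.design and self.n_genes > 0:
            raise ValueError("design must contain at least one cell")
        for cell in self.design:
            key = (cell.genotype, cell.stage)
            if key not in self.abundance:
                raise ValueError(f"abundance undefined for design cell {key}")
        if self.batch_sd_log2 < 0:
            raise ValueError("batch_sd_log2 must be nonnegative")
        for lo, hi in (self.baseline_log2_mean_range, self.dispersion_range,
                       self.libsize_range):
            if lo > hi:
                raise ValueError("range lower bound exceeds upper bound")


def recovery_benchmark_config(seed: int = 0) -> BulkSimConfig:
    """The standard benchmark for screen/module recovery.

    200 planted signature genes among 2200, expressed at marker-gene
    levels (baseline mean >= 2^7 counts): cell-type markers of an abundant
    population sit well above the detection floor, and three-replicate
    designs have no power below roughly 100 mean counts for two-fold
    effects.
    """
    return BulkSimConfig(
        n_genes=2200,
        planted_modules=[PlantedModule("BG", 200)],
        baseline_log2_mean_range=(7.0, 10.0),
        seed=seed,
    )


@dataclass
class GroundTruth:
    """What the simulator actually planted, for downstream scoring."""

    module_membership: dict[str, str]        # gene -> module name or "background"
    abundance: pd.DataFrame                  # (genotype, stage) x 1, column "a"
    baseline_log2_mean: pd.Series
    dispersion: pd.Series
    effect_size_log2: float
    true_de: dict[str, set[str]] = field(default_factory=dict)

    def de_genes(self, num: tuple[str, str], den: tuple[str, str]) -> set[str]:
        """Genes truly differential between two design cells.

        A planted gene is differential whenever its module's abundance
        differs between the two cells and the effect size is nonzero.
        """
        key = f"{num[0]}_{num[1]}_vs_{den[0]}_{den[1]}"
        return self.true_de.get(key, set())


def _nb_draw(rng: np.random.Generator, mu: np.ndarray,
             alpha: np.ndarray) -> np.ndarray:
    """Gamma-Poisson mixture: lambda ~ Gamma(1/alpha, alpha*mu), y ~ Poisson."""
    shape = 1.0 / alpha
    lam = rng.gamma(shape, alpha * mu)
    return rng.poisson(lam)


def simulate_bulk_experiment(
    config: BulkSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a count matrix, sample metadata, and ground truth.

    Expected count for gene i in sample j is
    ``libsize_j * batch_factor_ij * 2 ** (baseline_i + beta * a_j * planted_i)``
    with negative-binomial sampling at per-gene dispersion alpha.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n)]

    membership = {g: "background" for g in gene_ids}
    profiles: dict[str, Mapping[tuple[str, str], float]] = {}
    cursor = 0
    for mod in config.planted_modules:
        for g in gene_ids[cursor:cursor + mod.size]:
            membership[g] = mod.name
        profiles[mod.name] = mod.effect_profile or config.abundance
        cursor += mod.size

    baseline = rng.uniform(*config.baseline_log2_mean_range, size=n)
    alpha = rng.uniform(*config.dispersion_range, size=n)

    samples: list[str] = []
    meta_rows: list[dict] = []
    for cell in config.design:
        for r in range(cell.n_replicates):
            sid = f"{cell.genotype}_{cell.stage}_r{r + 1}_{cell.batch}"
            samples.append(sid)
            meta_rows.append({"sample_id": sid, "genotype": cell.genotype,
                              "stage": cell.stage, "batch": cell.batch})
    meta = pd.DataFrame(meta_rows).set_index("sample_id") if meta_rows else \
        pd.DataFrame(columns=["genotype", "stage", "batch"])

    if n == 0 or not samples:
        counts = pd.DataFrame(np.zeros((n, len(samples)), dtype=int),
                              index=gene_ids, columns=samples)
        truth = GroundTruth({}, pd.DataFrame(columns=["a"]),
                            pd.Series(dtype=float), pd.Series(dtype=float),
                            config.effect_size_log2)
        return counts, meta, truth

    lo, hi = config.libsize_range
    libsize = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(samples)))

    batches = sorted({c.batch for c in config.design})
    batch_shift = {b: (rng.normal(0.0, config.batch_sd_log2, size=n)
                       if config.batch_sd_log2 > 0 else np.zeros(n))
                   for b in batches}

    beta = config.effect_size_log2
    is_planted = np.array([membership[g] != "background" for g in gene_ids])
    mod_of_gene = np.array([membership[g] for g in gene_ids])

    counts = np.zeros((n, len(samples)), dtype=np.int64)
    for j, sid in enumerate(samples):
        g_j, s_j, b_j = meta.loc[sid, ["genotype", "stage", "batch"]]
        log2mu = baseline + batch_shift[b_j]
        if is_planted.any() and beta != 0.0:
            a_vec = np.zeros(n)
            for name, prof in profiles.items():
                a_vec[mod_of_gene == name] = prof[(g_j, s_j)]
            log2mu = log2mu + beta * a_vec
        mu = libsize[j] * np.exp2(log2mu)
        counts[:, j] = _nb_draw(rng, mu, alpha)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=samples)

    abundance_df = pd.DataFrame(
        [{"genotype": g, "stage": s, "a": a}
         for (g, s), a in config.abundance.items()]
    ).set_index(["genotype", "stage"])

    true_de: dict[str, set[str]] = {}
    cells = sorted({(c.genotype, c.stage) for c in config.design})
    for num in cells:
        for den in cells:
            if num == den:
                continue
            key = f"{num[0]}_{num[1]}_vs_{den[0]}_{den[1]}"
            de: set[str] = set()
            if beta != 0.0:
                for name, prof in profiles.items():
                    if prof[num] != prof[den]:
                        de.update(g for g in gene_ids
                                  if membership[g] == name)
            true_de[key] = de

    truth = GroundTruth(
        module_membership=membership,
        abundance=abundance_df,
        baseline_log2_mean=pd.Series(baseline, index=gene_ids),
        dispersion=pd.Series(alpha, index=gene_ids),
        effect_size_log2=beta,
        true_de=true_de,
    )
    return counts_df, meta, truth


@dataclass(frozen=True)
class CellTypeSpec:
    name: str
    n_cells: int
    signature_genes: tuple[str, ...] = ()
    signature_log2_shift: float = 0.0


@dataclass
class SingleCellSimConfig:
    cell_types: list[CellTypeSpec]
    n_genes: int = 500
    baseline_log2_mean_range: tuple[float, float] = (-1.0, 4.0)
    dispersion_range: tuple[float, float] = (0.1, 0.5)
    libsize_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        names = [t.name for t in self.cell_types]
        if len(names) != len(set(names)):
            raise ValueError("duplicate cell-type names")
        for t in self.cell_types:
            if t.n_cells < 1:
                raise ValueError(f"cell type {t.name} needs n_cells >= 1")


def simulate_single_cells(
    config: SingleCellSimConfig,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a gene x cell count matrix with type-specific signatures.

    Signature genes of a type get a ``signature_log2_shift`` added to their
    baseline log2 mean in cells of that type only.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n)]
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    baseline = rng.uniform(*config.baseline_log2_mean_range, size=n)
    alpha = rng.uniform(*config.dispersion_range, size=n)

    cells: list[str] = []
    labels: list[str] = []
    cols: list[np.ndarray] = []
    for spec in config.cell_types:
        shift = np.zeros(n)
        for g in spec.signature_genes:
            if g in gene_pos:
                shift[gene_pos[g]] = spec.signature_log2_shift
        log2mu = baseline + shift
        base_mu = np.exp2(log2mu)
        lo, hi = config.libsize_range
        for c in range(spec.n_cells):
            cid = f"{spec.name}_c{c + 1:04d}"
            cells.append(cid)
            labels.append(spec.name)
            lib = np.exp(rng.uniform(np.log(lo), np.log(hi)))
            cols.append(_nb_draw(rng, lib * base_mu, alpha))

    counts = pd.DataFrame(np.column_stack(cols) if cols else
                          np.zeros((n, 0), dtype=int),
                          index=gene_ids, columns=cells)
    return counts, pd.Series(labels, index=cells, name="cell_type")


@dataclass
class OrthologMap:
    """Records (idA, idB, homology_type, biotype)."""

    records: pd.DataFrame

    def one2one(self) -> pd.DataFrame:
        return self.records[self.records["homology_type"] == "one2one"]


def simulate_species_pair(
    config_a: BulkSimConfig,
    config_b: BulkSimConfig,
    shared_modules: Sequence[PlantedModule],
    n_orthologs: int,
    many2many_frac: float = 0.0,
    rrna_frac: float = 0.0,
    mito_frac: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, OrthologMap]:
    """Two bulk datasets sharing planted modules over mapped orthologs.

    The first ``n_orthologs`` genes of each species are paired one-to-one;
    shared modules are planted over the first mapped genes in both species
    so that their coexpression structure is preserved across the pair.
    Decoy many-to-many pairs and rRNA/mito-flagged genes are appended or
    flagged at exact counts (``round(frac * n_orthologs)``).
    """
    shared = list(shared_modules)
    total_shared = sum(m.size for m in shared)
    if n_orthologs > min(config_a.n_genes, config_b.n_genes):
        raise ValueError("n_orthologs exceeds a species' gene count")
    if total_shared > n_orthologs:
        raise ValueError("shared modules do not fit inside the ortholog set")

    cfg_a = BulkSimConfig(**{**config_a.__dict__,
                             "planted_modules": shared,
                             "seed": config_a.seed})
    cfg_b = BulkSimConfig(**{**config_b.__dict__,
                             "planted_modules": shared,
                             "seed": config_b.seed})
    counts_a, _, _ = simulate_bulk_experiment(cfg_a)
    counts_b, _, _ = simulate_bulk_experiment(cfg_b)

    counts_a.index = [f"A_{g}" for g in counts_a.index]
    counts_b.index = [f"B_{g}" for g in counts_b.index]

    rng = np.random.default_rng(seed)
    rows = []
    ids_a = list(counts_a.index[:n_orthologs])
    ids_b = list(counts_b.index[:n_orthologs])
    n_rrna = int(round(rrna_frac * n_orthologs))
    n_mito = int(round(mito_frac * n_orthologs))
    flagged = rng.permutation(n_orthologs)[: n_rrna + n_mito] \
        if n_rrna + n_mito else np.array([], dtype=int)
    biotype = np.full(n_orthologs, "other", dtype=object)
    biotype[flagged[:n_rrna]] = "rRNA"
    biotype[flagged[n_rrna:]] = "mito"
    for i in range(n_orthologs):
        rows.append({"idA": ids_a[i], "idB": ids_b[i],
                     "homology_type": "one2one", "biotype": biotype[i]})
    n_decoy = int(round(many2many_frac * n_orthologs))
    for d in range(n_decoy):
        i = int(rng.integers(n_orthologs))
        j = int(rng.integers(n_orthologs))
        rows.append({"idA": ids_a[i], "idB": ids_b[j],
                     "homology_type": "many2many", "biotype": "other"})
    omap = OrthologMap(pd.DataFrame(rows).drop_duplicates(["idA", "idB"]))
    return counts_a, counts_b, omap


@dataclass
class IshSimConfig:
    """In-situ scoring rubric simulation (0 = no signal in the Purkinje
    cell layer ... 3 = Bergmann-glia specific)."""

    true_positive_set: frozenset[str]
    score_distribution_positive: tuple[float, float, float, float]
    score_distribution_negative: tuple[float, float, float, float]
    n_genes_scored: int
    seed: int = 0

    def validate(self) -> None:
        for dist in (self.score_distribution_positive,
                     self.score_distribution_negative):
            if len(dist) != 4 or any(p < 0 for p in dist):
                raise ValueError("score distribution must be 4 nonnegative probabilities")
            if abs(sum(dist) - 1.0) > 1e-9:
                raise ValueError("score distribution must sum to 1")
        if self.n_genes_scored < 0:
            raise ValueError("n_genes_scored must be nonnegative")


def simulate_ish_scores(config: IshSimConfig) -> pd.DataFrame:
    """Draw a blinded scoring table: gene, is_true_positive, score in 0-3.

    True positives score from the positive distribution, the rest from the
    negative one. The first genes of the table are the true positives (up
    to ``n_genes_scored``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    positives = sorted(config.true_positive_set)[: config.n_genes_scored]
    n_neg = config.n_genes_scored - len(positives)
    genes = positives + [f"neg{i:05d}" for i in range(n_neg)]
    is_pos = np.array([g in config.true_positive_set for g in genes],
                      dtype=bool)
    scores = np.empty(len(genes), dtype=int)
    if is_pos.any():
        scores[is_pos] = rng.choice(
            4, size=int(is_pos.sum()), p=config.score_distribution_positive)
    if (~is_pos).any():
        scores[~is_pos] = rng.choice(
            4, size=int((~is_pos).sum()), p=config.score_distribution_negative)
    return pd.DataFrame({"gene": genes, "true_positive": is_pos,
                         "score": scores}).set_index("gene")
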