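"""Synthetic datasets with planted module structure.

The generator emulates the statistical shape of a whole-blood trisomy-21
cohort feeding the pathway-guided module pipeline: a low-rank gene x sample
expression matrix whose loadings partially align with prior gene sets,
karyotype shifts on a chosen subset of module activities, per-trait TWAS
p-values enriched in the top-loading genes of chosen modules, block-correlated
expression noise, and comorbidity labels driven (through a logistic model) by
one module's activity among T21 samples. Every planted effect is recorded in a
:class:`SyntheticTruth` so downstream stages have parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

from . import io
from .errors import InvalidConfigError

_AUTOSOMES = [str(c) for c in range(1, 23) if c != 21]


def _default_trait_plants() -> tuple:
    return (
        ("erythrocyte_count", 0, 1.5),
        ("lymphocyte_count", 1, 1.5),
        ("standing_height", 0, 0.0),
        ("heel_bone_density", 1, 0.0),
    )


def _default_comorbidity_plants() -> tuple:
    return (
        ("pulmonary_hypertension", 2, 0.0, 3.0),
        ("sleep_apnea", 0, -0.5, 0.0),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic cohort.

    Defaults describe the study conditions used throughout the test-suite:
    2,000 genes, 300 T21 + 100 D21 samples, 20 planted modules of which three
    (indices 0-2) carry a 1.0 SD karyotype shift, two traits enriched (effect
    1.5 on the half-normal score scale) in modules 0 and 1 plus two null
    traits, and one comorbidity driven by module 2 with logistic slope 3 plus
    one null comorbidity. Expression noise is block-correlated (blocks of 10
    genes, compound-symmetric rho = 0.3).
    """

    n_genes: int = 2000
    n_samples_t21: int = 300
    n_samples_d21: int = 100
    k_true: int = 20
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (20, 60)
    frac_aligned: float = 0.75
    sgm_indices: tuple[int, ...] = (0, 1, 2)
    sgm_effect: float = 1.0
    noise_sd_expression: float = 0.3
    noise_sd_loadings: float = 0.1
    trait_plants: tuple = field(default_factory=_default_trait_plants)
    corr_block_size: int = 10
    corr_rho: float = 0.3
    comorbidity_plants: tuple = field(default_factory=_default_comorbidity_plants)
    frac_chr21: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.pathway_size_range
        if min(self.n_genes, self.n_samples_t21, self.n_samples_d21,
               self.k_true, self.n_pathways, self.corr_block_size) < 1:
            raise InvalidConfigError("all dimensions must be positive")
        if not (1 <= lo <= hi):
            raise InvalidConfigError("pathway_size_range must satisfy 1 <= min <= max")
        if hi > self.n_genes:
            raise InvalidConfigError(
                f"pathway size range ({lo},{hi}) exceeds the gene universe ({self.n_genes})")
        if not 0.0 <= self.frac_aligned <= 1.0:
            raise InvalidConfigError("frac_aligned must lie in [0,1]")
        if not 0.0 <= self.corr_rho < 1.0:
            raise InvalidConfigError("corr_rho must lie in [0,1)")
        if min(self.noise_sd_expression, self.noise_sd_loadings) < 0:
            raise InvalidConfigError("noise SDs must be nonnegative")
        if not 0.0 <= self.frac_chr21 <= 1.0:
            raise InvalidConfigError("frac_chr21 must lie in [0,1]")
        for idx in self.sgm_indices:
            if not 0 <= idx < self.k_true:
                raise InvalidConfigError(f"sgm index {idx} outside [0,{self.k_true})")
        for trait_id, m, _eff in self.trait_plants:
            if not 0 <= m < self.k_true:
                raise InvalidConfigError(f"trait {trait_id!r} plants module {m} >= k_true")
        for com_id, m, _b0, _b1 in self.comorbidity_plants:
            if not 0 <= m < self.k_true:
                raise InvalidConfigError(f"comorbidity {com_id!r} plants module {m} >= k_true")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated cohort."""

    Z_true: pd.DataFrame            # genes x k_true, nonnegative
    B_true: pd.DataFrame            # k_true x samples
    C_true: pd.DataFrame            # genes x pathways, binary
    U_true: pd.DataFrame            # pathways x k_true, nonnegative sparse
    karyotype: pd.Series            # per sample, "T21" / "D21"
    planted_sgm: frozenset          # module indices with karyotype shift
    planted_trait_pairs: frozenset  # {(trait_id, module_index)} with effect > 0
    planted_comorbidity_pairs: frozenset  # {(comorbidity_id, module_index)} slope != 0
    Sigma_true: np.ndarray          # genes x genes correlation of expression noise


@dataclass
class SyntheticDataset:
    """The five pipeline inputs plus the planted truth."""

    expression: pd.DataFrame        # genes x samples
    metadata: pd.DataFrame          # index sample_id; karyotype + comorbidity columns
    twas: pd.DataFrame              # gene_id, trait_id, pvalue
    gene_annotation: pd.DataFrame   # gene_id, chromosome
    priors: dict                    # gene-set name -> member gene list (GMT content)
    truth: SyntheticTruth
    config: SimulationConfig


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _module_names(k: int) -> list[str]:
    return [f"LV{i + 1}" for i in range(k)]


def _prior_matrix(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = cfg.pathway_size_range
    genes = pd.Index(_gene_ids(cfg.n_genes), name="gene_id")
    C = np.zeros((cfg.n_genes, cfg.n_pathways), dtype=np.int8)
    for j in range(cfg.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(cfg.n_genes, size=size, replace=False)
        C[members, j] = 1
    cols = pd.Index([f"PW{j:03d}" for j in range(cfg.n_pathways)],
                    name="gene_set")
    return pd.DataFrame(C, index=genes, columns=cols)


def generate_prior_matrix(config: SimulationConfig) -> pd.DataFrame:
    """Binary gene x gene-set membership matrix, deterministic given the seed.

    Uses the same random stream position as :func:`generate_dataset`, so the
    returned matrix equals the ``C_true`` of the full dataset for an identical
    configuration.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    return _prior_matrix(config, rng)


def _block_noise(rng: np.random.Generator, g: int, s: int, block: int,
                 rho: float, sd: float) -> np.ndarray:
    """Compound-symmetric within-block noise, unit variance before sd scaling."""
    n_blocks = math.ceil(g / block)
    shared = rng.standard_normal((n_blocks, s))
    indep = rng.standard_normal((g, s))
    shared_full = np.repeat(shared, block, axis=0)[:g]
    return sd * (math.sqrt(rho) * shared_full + math.sqrt(1.0 - rho) * indep)


def block_correlation_matrix(n_genes: int, block: int, rho: float) -> np.ndarray:
    """Block-diagonal compound-symmetric correlation with unit diagonal (SPD for rho < 1)."""
    sigma = np.eye(n_genes)
    for start in range(0, n_genes, block):
        stop = min(start + block, n_genes)
        sigma[start:stop, start:stop] = rho
        np.fill_diagonal(sigma[start:stop, start:stop], 1.0)
    return sigma


def _top_frac_indices(values: np.ndarray, frac: float) -> np.ndarray:
    """Indices of the ceil(frac*n) largest |values|, ties broken by index order."""
    n = values.size
    n_top = math.ceil(frac * n)
    order = np.lexsort((np.arange(n), -np.abs(values)))
    return order[:n_top]


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Simulate a full cohort: expression, metadata, TWAS, annotation, priors, truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    g, k = config.n_genes, config.k_true
    n_t21, n_d21 = config.n_samples_t21, config.n_samples_d21
    s = n_t21 + n_d21
    genes = pd.Index(_gene_ids(g), name="gene_id")
    modules = pd.Index(_module_names(k), name="lv")
    samples = pd.Index([f"T21_{i + 1:04d}" for i in range(n_t21)]
                       + [f"D21_{i + 1:04d}" for i in range(n_d21)],
                       name="sample_id")

    C = _prior_matrix(config, rng)

    # sparse nonnegative pathway coefficients touching frac_aligned of modules
    n_aligned = int(round(config.frac_aligned * k))
    aligned = np.sort(rng.choice(k, size=n_aligned, replace=False))
    U = np.zeros((config.n_pathways, k))
    replace = config.n_pathways < n_aligned
    pw_choice = rng.choice(config.n_pathways, size=n_aligned, replace=replace)
    U[pw_choice, aligned] = 1.0

    Z = np.maximum(
        0.0, C.to_numpy(float) @ U + rng.normal(0.0, config.noise_sd_loadings, (g, k)))

    B = rng.standard_normal((k, s))
    if config.sgm_indices:
        B[np.asarray(config.sgm_indices), :n_t21] += config.sgm_effect

    noise = _block_noise(rng, g, s, config.corr_block_size,
                         config.corr_rho, config.noise_sd_expression)
    X = Z @ B + noise

    karyotype = pd.Series(["T21"] * n_t21 + ["D21"] * n_d21, index=samples,
                          name="karyotype")

    # TWAS table: half-normal score magnitudes, planted enrichment additive on
    # the top 1% loading genes of the chosen module.
    twas_rows = []
    planted_traits = set()
    for trait_id, m, eff in config.trait_plants:
        z = np.abs(rng.standard_normal(g))
        if eff > 0:
            z[_top_frac_indices(Z[:, m], 0.01)] += eff
            planted_traits.add((trait_id, m))
        pvals = np.clip(2.0 * (1.0 - ndtr(z)), 1e-300, 1.0)
        twas_rows.append(pd.DataFrame(
            {"gene_id": genes, "trait_id": trait_id, "pvalue": pvals}))
    twas = (pd.concat(twas_rows, ignore_index=True)
            if twas_rows else pd.DataFrame(columns=["gene_id", "trait_id", "pvalue"]))

    # comorbidity labels among T21 samples only; D21 left missing
    metadata = pd.DataFrame({"karyotype": karyotype})
    planted_coms = set()
    for com_id, m, b0, b1 in config.comorbidity_plants:
        prob = expit(b0 + b1 * B[m, :n_t21])
        labels = rng.binomial(1, prob).astype(float)
        col = np.full(s, np.nan)
        col[:n_t21] = labels
        metadata[com_id] = col
        if b1 != 0:
            planted_coms.add((com_id, m))

    # chromosome annotation: a configurable fraction on chr21, rest autosomal
    n_chr21 = int(round(config.frac_chr21 * g))
    chr21_idx = rng.choice(g, size=n_chr21, replace=False)
    chroms = rng.choice(_AUTOSOMES, size=g)
    chroms[chr21_idx] = "21"
    annotation = pd.DataFrame({"gene_id": genes, "chromosome": chroms})

    sigma = block_correlation_matrix(g, config.corr_block_size, config.corr_rho)

    priors = {name: list(C.index[C[name] == 1]) for name in C.columns}
    truth = SyntheticTruth(
        Z_true=pd.DataFrame(Z, index=genes, columns=modules),
        B_true=pd.DataFrame(B, index=modules, columns=samples),
        C_true=C,
        U_true=pd.DataFrame(U, index=C.columns, columns=modules),
        karyotype=karyotype,
        planted_sgm=frozenset(config.sgm_indices),
        planted_trait_pairs=frozenset(planted_traits),
        planted_comorbidity_pairs=frozenset(planted_coms),
        Sigma_true=sigma,
    )
    expression = pd.DataFrame(X, index=genes, columns=samples)
    return SyntheticDataset(expression=expression, metadata=metadata, twas=twas,
                            gene_annotation=annotation, priors=priors,
                            truth=truth, config=config)


def write_dataset(ds: SyntheticDataset, outdir: str | os.PathLike,
                  write_sigma: bool = False) -> None:
    """Serialize the five pipeline inputs plus a truth archive (TSV + JSON manifest).

    ``Sigma_true`` is reproducible from the manifest's block parameters and is
    only written on request (it is quadratic in the number of genes).
    """
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    seed = ds.config.seed
    io.write_table(ds.expression, os.path.join(outdir, "expression.tsv"),
                   seed=seed, index_label="gene_id")
    io.write_table(ds.metadata, os.path.join(outdir, "metadata.tsv"),
                   seed=seed, index_label="sample_id")
    io.write_table(ds.twas, os.path.join(outdir, "twas.tsv"), seed=seed, index=False)
    io.write_table(ds.gene_annotation, os.path.join(outdir, "gene_annotation.tsv"),
                   seed=seed, index=False)
    io.write_gmt(ds.priors, os.path.join(outdir, "priors.gmt"))

    truth_dir = os.path.join(outdir, "truth")
    os.makedirs(truth_dir, exist_ok=True)
    io.write_table(ds.truth.Z_true, os.path.join(truth_dir, "Z_true.tsv"),
                   seed=seed, index_label="gene_id")
    io.write_table(ds.truth.B_true, os.path.join(truth_dir, "B_true.tsv"),
                   seed=seed, index_label="lv")
    io.write_table(ds.truth.U_true, os.path.join(truth_dir, "U_true.tsv"),
                   seed=seed, index_label="gene_set")
    if write_sigma:
        io.write_table(pd.DataFrame(ds.truth.Sigma_true,
                                    index=ds.expression.index,
                                    columns=ds.expression.index),
                       os.path.join(truth_dir, "Sigma_true.tsv"),
                       seed=seed, index_label="gene_id")
    manifest = {
        "config": dataclasses.asdict(ds.config),
        "planted_sgm": sorted(ds.truth.planted_sgm),
        "planted_trait_pairs": sorted(map(list, ds.truth.planted_trait_pairs)),
        "planted_comorbidity_pairs": sorted(map(list, ds.truth.planted_comorbidity_pairs)),
        "sigma": {"structure": "block_compound_symmetric",
                  "block_size": ds.config.corr_block_size,
                  "rho": ds.config.corr_rho},
    }
    io.write_json(manifest, os.path.join(truth_dir, "manifest.json"))
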