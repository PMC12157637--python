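"""End-to-end orchestration: normalize, fit, annotate, associate, classify.

A single :class:`PipelineConfig` names the five inputs (expression TSV, GMT
priors, sample metadata TSV, TWAS TSV, gene-annotation TSV, optionally a
gene-gene correlation TSV) and the stage parameters; :func:`run_pipeline`
executes the stages in order, writes every stage table under the output
directory, and returns a machine-readable run report. A single master seed
fans out into per-stage streams so stages are individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import annotate as annotate_mod
from . import associate as associate_mod
from . import classify as classify_mod
from . import differential as diff_mod
from . import factorize, io
from .errors import (DegenerateDataError, GeneAlignmentError, InvalidConfigError,
                     InvalidInputError)

logger = logging.getLogger(__name__)

_STAGE_SEEDS = {"estimate_k": 1, "fit": 2, "alignment": 3, "classify": 4}


@dataclass
class PipelineConfig:
    """Inputs, stage parameters, and output location of one run.

    Threshold defaults follow the framework's conventions: SGM FDR 0.05 with
    |effect| 0.25, ORA FDR 0.05 on the top 5% of loadings, association FDR 0.1
    on the top 1% indicator, classification AUC/mAPS 0.65 with 50 balanced
    subsampling iterations.
    """

    expression: str = ""
    gmt: str = ""
    metadata: str = ""
    twas: str = ""
    gene_annotation: str = ""
    sigma: str | None = None
    outdir: str = "trisomod_out"
    k: int | str = "auto"
    frac: float = 0.7
    holdout_frac: float = 0.2
    n_permutations: int = 20
    pa_quantile: float = 0.95
    max_iter: int = 350
    tol: float = 5e-3
    ora_frac: float = 0.05
    ora_fdr: float = 0.05
    gls_top_frac: float = 0.01
    sgm_fdr: float = 0.05
    sgm_effect_threshold: float = 0.25
    assoc_fdr: float = 0.1
    auc_threshold: float = 0.65
    maps_threshold: float = 0.65
    iterations: int = 50
    membership_frac: float = 0.05
    seed: int = 0
    penalties: tuple[float, float, float] | None = None

    def validate(self) -> None:
        for name in ("expression", "gmt", "metadata", "twas", "gene_annotation"):
            path = getattr(self, name)
            if not path or not os.path.exists(path):
                raise InvalidConfigError(f"input file for {name!r} not found: {path!r}")
        if self.sigma is not None and not os.path.exists(self.sigma):
            raise InvalidConfigError(f"sigma file not found: {self.sigma!r}")
        for name in ("frac", "holdout_frac", "ora_frac", "gls_top_frac", "sgm_fdr",
                     "ora_fdr", "assoc_fdr", "auc_threshold", "maps_threshold",
                     "membership_frac"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0 and not (name == "frac" and v == 1.0):
                raise InvalidConfigError(f"{name}={v} must lie in (0,1)")
        if self.k != "auto" and (not isinstance(self.k, int) or self.k < 1):
            raise InvalidConfigError("k must be a positive integer or 'auto'")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        if "penalties" in raw and raw["penalties"] is not None:
            raw["penalties"] = tuple(raw["penalties"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d.get("penalties") is not None:
            d["penalties"] = list(d["penalties"])
        return d


@dataclass
class InputBundle:
    """Validated, gene/sample-harmonized in-memory inputs."""

    expression: pd.DataFrame
    priors: dict[str, list[str]]
    metadata: pd.DataFrame
    twas: pd.DataFrame
    gene_annotation: pd.Series          # gene -> chromosome, annotated genes only
    sigma: pd.DataFrame | None
    log: dict = field(default_factory=dict)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def read_inputs(config: PipelineConfig) -> InputBundle:
    """Read and harmonize the inputs.

    Genes are kept if present in the expression matrix (the quantified
    universe); GMT members and TWAS rows for unknown genes are dropped with
    counts logged, genes without chromosome annotation are retained for
    factorization but excluded from the chromosome-21 test.
    """
    config.validate()
    expr = io.read_matrix(config.expression)
    if expr.columns.has_duplicates:
        raise InvalidInputError("duplicate sample identifiers in expression matrix")
    meta = io.read_matrix(config.metadata)
    common_samples = expr.columns.intersection(meta.index)
    if len(common_samples) == 0:
        raise GeneAlignmentError("no sample identifiers shared by expression and metadata")
    dropped_samples = len(expr.columns) - len(common_samples)
    expr = expr[common_samples]
    meta = meta.loc[common_samples]

    genes = expr.index
    priors_raw = io.read_gmt(config.gmt)
    priors: dict[str, list[str]] = {}
    dropped_members = 0
    for name, members in priors_raw.items():
        known = [g for g in members if g in genes]
        dropped_members += len(members) - len(known)
        priors[name] = known
    if not any(priors.values()):
        raise GeneAlignmentError("no GMT member gene matches the expression matrix")

    twas = io.read_table(config.twas)
    n_twas = len(twas)
    twas = twas[twas["gene_id"].isin(genes)]

    ann = io.read_table(config.gene_annotation)
    if ann["gene_id"].duplicated().any():
        raise InvalidInputError("duplicate gene identifiers in annotation table")
    ann = ann[ann["gene_id"].isin(genes)]
    chroms = ann.set_index("gene_id")["chromosome"].astype(str)

    sigma = None
    if config.sigma is not None:
        sigma = io.read_matrix(config.sigma)
        missing = genes.difference(sigma.index)
        if len(missing):
            raise GeneAlignmentError(
                f"correlation matrix misses {len(missing)} expression genes")
        sigma = sigma.loc[genes, genes]

    log = {
        "n_genes": int(len(genes)),
        "n_samples": int(len(common_samples)),
        "n_samples_dropped": int(dropped_samples),
        "n_gmt_members_dropped": int(dropped_members),
        "n_twas_rows_dropped": int(n_twas - len(twas)),
        "n_genes_unannotated": int(len(genes) - len(chroms)),
    }
    logger.info("harmonized inputs: %s", log)
    return InputBundle(expression=expr, priors=priors, metadata=meta, twas=twas,
                       gene_annotation=chroms, sigma=sigma, log=log)


def _stage_seed(master: int, stage: str) -> int:
    return int(np.random.SeedSequence([master, _STAGE_SEEDS[stage]])
               .generate_state(1)[0] % (2 ** 31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and write results under ``config.outdir``.

    Returns the run report (also written as ``report.json``): per-stage row
    counts, selected module lists, convergence diagnostics, version, config
    echo and input checksums — enough to reproduce the run exactly.
    """
    bundle = read_inputs(config)
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    seed = config.seed
    report: dict = {
        "version": io.__version__,
        "seed": seed,
        "config": config.to_dict(),
        "input_checksums": {
            name: _sha256(getattr(config, name))
            for name in ("expression", "gmt", "metadata", "twas", "gene_annotation")
            if getattr(config, name)
        },
        "harmonization": bundle.log,
        "stages": {},
    }

    # --- normalize -------------------------------------------------------
    Xn = factorize.zscore_rows(bundle.expression)

    # --- component number ------------------------------------------------
    if config.k == "auto":
        k = factorize.estimate_num_components(
            Xn, n_permutations=config.n_permutations, quantile=config.pa_quantile,
            seed=_stage_seed(seed, "estimate_k"))
        k = max(k, 1)
    else:
        k = int(config.k)
    report["stages"]["estimate_k"] = {"k": k, "auto": config.k == "auto"}

    # --- factorization with prior hold-out -------------------------------
    C_full = factorize.prior_matrix_from_sets(bundle.priors, Xn.index)
    align_seed = _stage_seed(seed, "alignment")
    C_masked, _ = factorize.mask_prior(C_full, config.holdout_frac, align_seed)
    model = factorize.fit(Xn, C_masked, k=k, frac=config.frac,
                          penalties=config.penalties, max_iter=config.max_iter,
                          tol=config.tol, seed=_stage_seed(seed, "fit"))
    model.save(os.path.join(outdir, "model"), seed=seed)
    report["stages"]["fit"] = {
        "k": k, "converged": model.converged, "n_iter": model.n_iter,
        "penalties": list(model.penalties),
        "final_objective": model.objective_trace[-1],
    }

    alignment = factorize.pathway_alignment(model, C_full, config.holdout_frac,
                                            align_seed)
    io.write_table(alignment, os.path.join(outdir, "alignment.tsv"),
                   seed=seed, index=False)
    report["stages"]["alignment"] = {
        "n_pairs": int(len(alignment)),
        "n_aligned": int(((alignment["fdr"] < 0.05) & (alignment["auc"] > 0.6)).sum())
        if len(alignment) else 0,
    }

    # --- differential module activity ------------------------------------
    modules_table = diff_mod.test_differential_activity(
        model.B, bundle.metadata["karyotype"])
    modules_table = diff_mod.select_sgm(modules_table, config.sgm_fdr,
                                        config.sgm_effect_threshold)
    io.write_table(modules_table, os.path.join(outdir, "modules.tsv"), seed=seed)
    sgm = list(modules_table.index[modules_table["is_sgm"]])
    top_sgm = list(modules_table.index[modules_table["is_top_sgm"]])
    report["stages"]["differential"] = {
        **diff_mod.summarize_sgm(modules_table),
        "sgm": sgm, "top_sgm": top_sgm,
        "effect_convention": diff_mod.EFFECT_CONVENTION,
    }

    # --- chromosome-21 representation ------------------------------------
    annotated = bundle.gene_annotation.index
    try:
        fisher = diff_mod.chr21_representation_test(
            model.Z.loc[annotated], modules_table["is_sgm"],
            bundle.gene_annotation, config.membership_frac)
        chr21 = {"table": fisher.table.tolist(), "odds_ratio": fisher.odds_ratio,
                 "pvalue": fisher.pvalue, "sidedness": fisher.sidedness}
    except DegenerateDataError as exc:
        chr21 = {"skipped": str(exc)}
    io.write_json(chr21, os.path.join(outdir, "chr21_fisher.json"))
    report["stages"]["chr21_test"] = chr21

    # --- pathway over-representation -------------------------------------
    ora = annotate_mod.annotate_modules(model.Z, bundle.priors,
                                        universe=set(Xn.index.astype(str)),
                                        frac=config.ora_frac,
                                        fdr_threshold=config.ora_fdr)
    io.write_table(ora, os.path.join(outdir, "ora.tsv"), seed=seed, index=False)
    report["stages"]["ora"] = {"n_pairs": int(len(ora)),
                               "n_significant": int(ora["significant"].sum())}

    # --- module-trait association ----------------------------------------
    if bundle.sigma is not None:
        sigma = bundle.sigma
    else:
        sigma = pd.DataFrame(np.corrcoef(Xn.to_numpy()), index=Xn.index,
                             columns=Xn.index)
    assoc = associate_mod.associate_all(
        model.Z, bundle.twas, sigma, modules=top_sgm,
        top_frac=config.gls_top_frac, fdr_threshold=config.assoc_fdr)
    io.write_table(assoc, os.path.join(outdir, "associations.tsv"),
                   seed=seed, index=False)
    links = assoc[assoc["significant"]] if len(assoc) else assoc
    report["stages"]["association"] = {
        "n_pairs": int(len(assoc)),
        "n_links": int(len(links)),
        "links": [[r.lv, r.trait] for r in links.itertuples()] if len(links) else [],
        "modules_with_links": sorted(set(links["lv"])) if len(links) else [],
    }

    # --- comorbidity classification --------------------------------------
    metrics = classify_mod.evaluate_modules(
        model.B, bundle.metadata, modules=sgm,
        auc_threshold=config.auc_threshold, maps_threshold=config.maps_threshold,
        iterations=config.iterations, seed=_stage_seed(seed, "classify"))
    io.write_table(metrics, os.path.join(outdir, "classification.tsv"),
                   seed=seed, index=False)
    passing = metrics[metrics["passes"]] if len(metrics) else metrics
    report["stages"]["classification"] = {
        "n_pairs": int(len(metrics)),
        "n_passing": int(len(passing)),
        "passing": [[r.lv, r.comorbidity] for r in passing.itertuples()]
        if len(passing) else [],
        "passing_modules": sorted(set(passing["lv"])) if len(passing) else [],
    }

    io.write_json(report, os.path.join(outdir, "report.json"))
    return report
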