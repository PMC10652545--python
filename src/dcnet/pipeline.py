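"""End-to-end orchestration: align → per-group networks → jackknife → regression → adjustment.

The pipeline is deterministic for fixed inputs and configuration,
regardless of the worker count: every stochastic-looking component (fast-S
subsampling) uses a fixed internal seed, and leave-one-out fits are pure
functions of the reduced data.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

import dcnet
from dcnet.adjust import AdjustmentConfig, adjust_results, sig_dc_genes
from dcnet.io import PhenotypeTable, align_and_split
from dcnet.network import NetworkConfig
from dcnet.pseudovalue import assemble_pseudovalues, jackknife_pseudovalues
from dcnet.regression import RegressionConfig, build_design, fit_all_genes

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_analysis"]


@dataclass
class RunConfig:
    """Complete, serializable description of an analysis run."""

    network: NetworkConfig = field(default_factory=NetworkConfig)
    regression: RegressionConfig = field(default_factory=RegressionConfig)
    adjustment: AdjustmentConfig = field(default_factory=AdjustmentConfig)
    jobs: int = 1
    seed: int = 0  # reserved for stochastic modules; the core pipeline is deterministic
    output_dir: str | None = None
    group_a_level: str | None = None
    group_b_level: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "network" in d and isinstance(d["network"], dict):
            d["network"] = NetworkConfig(**d["network"])
        if "regression" in d and isinstance(d["regression"], dict):
            d["regression"] = RegressionConfig(**d["regression"])
        if "adjustment" in d and isinstance(d["adjustment"], dict):
            d["adjustment"] = AdjustmentConfig(**d["adjustment"])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _sha256_df(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(sep="\t").encode()
    ).hexdigest()


def run_analysis(
    expr: pd.DataFrame,
    pheno: PhenotypeTable,
    config: RunConfig | None = None,
    covariates: list[str] | None = None,
):
    """Run the full differential-connectivity analysis.

    Parameters
    ----------
    expr, pheno
        Samples × genes expression and phenotype tables (sample ids are
        intersected and aligned here).
    covariates
        Optional subset of phenotype columns to adjust for (default: all
        non-group columns).

    Returns a completed result set (coefficients, p-values, adjusted
    p-values; genes × predictors). If ``config.output_dir`` is set, writes
    coefficients.tsv, pvalues.tsv, adj_pvalues.tsv, dc_genes.tsv and a JSON
    run manifest there.
    """
    config = config or RunConfig()
    t0 = time.perf_counter()

    if covariates is not None:
        missing = [c for c in covariates if c not in pheno.data.columns]
        if missing:
            raise ValueError(f"unknown covariate column(s): {missing}")
        keep = [pheno.group_variable] + [c for c in covariates if c != pheno.group_variable]
        pheno = PhenotypeTable(
            data=pheno.data[keep],
            group_variable=pheno.group_variable,
            numeric_columns=[c for c in pheno.numeric_columns if c in keep],
            categorical_columns=[c for c in pheno.categorical_columns if c in keep],
        )

    expr2, pheno2, assignment = align_and_split(
        expr, pheno, config.group_a_level, config.group_b_level
    )
    logger.info(
        "aligned %d samples (%d + %d) × %d genes [%.2fs]",
        len(expr2), assignment.group_a_indices.size,
        assignment.group_b_indices.size, expr2.shape[1], time.perf_counter() - t0,
    )

    t1 = time.perf_counter()
    expr_a = expr2.iloc[assignment.group_a_indices]
    expr_b = expr2.iloc[assignment.group_b_indices]
    psv_a = jackknife_pseudovalues(expr_a, config.network, n_jobs=config.jobs)
    psv_b = jackknife_pseudovalues(expr_b, config.network, n_jobs=config.jobs)
    psv = assemble_pseudovalues(psv_a, psv_b, assignment)
    logger.info("jackknife pseudo-values done [%.2fs]", time.perf_counter() - t1)

    t2 = time.perf_counter()
    design = build_design(pheno2, assignment)
    results = fit_all_genes(
        psv, design, group_predictor=pheno2.group_variable,
        config=config.regression, n_jobs=config.jobs,
    )
    for gene, flag in results.flags.items():
        logger.warning("gene %s: %s", gene, flag)
    logger.info("per-gene robust regressions done [%.2fs]", time.perf_counter() - t2)

    results = adjust_results(results, config.adjustment)

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.coefficients.to_csv(out / "coefficients.tsv", sep="\t", index_label="gene_id", float_format="%.17g")
        results.pvalues.to_csv(out / "pvalues.tsv", sep="\t", index_label="gene_id", float_format="%.17g")
        results.adj_pvalues.to_csv(out / "adj_pvalues.tsv", sep="\t", index_label="gene_id", float_format="%.17g")
        dc = sig_dc_genes(results, alpha=config.adjustment.alpha)
        dc.to_csv(out / "dc_genes.tsv", sep="\t")
        manifest = {
            "package": "dcnet",
            "version": dcnet.__version__,
            "config": config.to_dict(),
            "covariates": covariates,
            "inputs": {
                "expression_sha256": _sha256_df(expr),
                "phenotype_sha256": _sha256_df(pheno.data),
                "n_samples": int(expr2.shape[0]),
                "n_genes": int(expr2.shape[1]),
                "group_levels": [str(x) for x in assignment.level_labels],
            },
            "library_versions": {
                "numpy": __import__("numpy").__version__,
                "pandas": pd.__version__,
                "scipy": __import__("scipy").__version__,
            },
            "gene_flags": {str(k): v for k, v in results.flags.items()},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    logger.info("analysis complete [%.2fs total]", time.perf_counter() - t0)
    return results
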