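"""Multiple-testing adjustment and DC-gene extraction.

The default adjustment is empirical Bayes screening (EBS): the p-values are
modelled as a two-group mixture f(p) = pi0 · 1 + (1 − pi0) · f1(p); the
marginal density f is estimated by Gaussian kernel density estimation on
the probit scale (transform, estimate, back-transform with the Jacobian),
pi0 is read off the fitted density near p = 1, and each p-value is mapped
to its estimated posterior null probability min(1, pi0 / f(p)). A final
isotonic-regression pass enforces monotone non-decreasing adjusted values
in p. Benjamini–Hochberg step-up is available as a bit-reproducible
fallback and is used automatically when the family is too small (< 10) or
degenerate for density estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression

logger = logging.getLogger(__name__)

__all__ = [
    "AdjustmentConfig",
    "bh_adjust",
    "ebs_adjust",
    "adjust_results",
    "sig_dc_genes",
    "sig_dc_gene_names",
    "extract",
]

_PCLIP = 1e-10  # probit transform needs p strictly inside (0, 1)


@dataclass(frozen=True)
class AdjustmentConfig:
    """Adjustment method and knobs.

    method : "ebs" (default, posterior null probability screening) or "bh".
    alpha : significance level for DC calls, default 0.05.
    ebs_bandwidth : KDE bandwidth factor on the probit scale, or "auto"
        (Scott's rule).
    pi0_cap : upper cap for the estimated null proportion.
    """

    method: str = "ebs"
    alpha: float = 0.05
    ebs_bandwidth: float | str = "auto"
    pi0_cap: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.method not in ("ebs", "bh"):
            raise ValueError(f"unknown adjustment method {self.method!r}")
        if not 0.0 < self.pi0_cap <= 1.0:
            raise ValueError("pi0_cap must be in (0, 1]")


def _validate_pvals(pvals) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be one-dimensional")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (clipped at 1)."""
    p = _validate_pvals(pvals)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def ebs_adjust(pvals, config: AdjustmentConfig | None = None) -> np.ndarray:
    """Empirical Bayes screening: estimated posterior null probabilities.

    Falls back to :func:`bh_adjust` (with a warning) when the family has
    fewer than 10 members or the p-values are all identical, where density
    estimation has no mass to work with.
    """
    config = config or AdjustmentConfig()
    p = _validate_pvals(pvals)
    m = p.size
    if m < 10:
        logger.warning("EBS needs >= 10 p-values (got %d); using BH instead", m)
        return bh_adjust(p)
    if np.all(p == p[0]):
        logger.warning("degenerate (constant) p-value family; using BH instead")
        return bh_adjust(p)

    pc = np.clip(p, _PCLIP, 1.0 - _PCLIP)
    z = stats.norm.ppf(pc)
    bw = None if config.ebs_bandwidth == "auto" else float(config.ebs_bandwidth)
    kde = stats.gaussian_kde(z, bw_method=bw)

    def f_hat(pv: np.ndarray) -> np.ndarray:
        zv = stats.norm.ppf(np.clip(pv, _PCLIP, 1.0 - _PCLIP))
        return kde(zv) / stats.norm.pdf(zv)

    # null proportion from the fitted density near p = 1, capped
    grid = np.linspace(0.95, 1.0, 26)
    pi0 = float(np.median(f_hat(grid)))
    pi0 = min(max(pi0, _PCLIP), config.pi0_cap)

    with np.errstate(divide="ignore"):
        post = np.minimum(1.0, pi0 / f_hat(p))

    # posterior null probability should not decrease in p
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True)
    adj = iso.fit_transform(p, post)
    return np.clip(np.asarray(adj, dtype=float), 0.0, 1.0)


def adjust_results(results, config: AdjustmentConfig | None = None):
    """Fill ``results.adj_pvalues``, adjusting each predictor's family separately.

    Each predictor's p gene-level p-values form one family (the output then
    has the same gene × predictor shape as the raw p-values).
    """
    config = config or AdjustmentConfig()
    fn = ebs_adjust if config.method == "ebs" else lambda p, _=None: bh_adjust(p)
    adj = {
        col: fn(results.pvalues[col].to_numpy(), config)
        for col in results.pvalues.columns
    }
    results.adj_pvalues = pd.DataFrame(
        adj, index=results.pvalues.index, columns=results.pvalues.columns
    )
    return results


def _require_predictor(results, predictor: str) -> None:
    if predictor not in results.pvalues.columns:
        raise KeyError(
            f"unknown predictor {predictor!r}; available: "
            f"{list(results.pvalues.columns)}"
        )


def sig_dc_genes(results, group_predictor: str | None = None, alpha: float = 0.05) -> pd.DataFrame:
    """Genes whose adjusted group p-value is below ``alpha`` (strict), with values.

    Sorted by gene id for determinism.
    """
    if results.adj_pvalues is None:
        raise ValueError("adjusted p-values have not been computed yet")
    pred = group_predictor or results.group_predictor
    _require_predictor(results, pred)
    col = results.adj_pvalues[pred]
    hits = col[col < alpha].sort_index(key=lambda ix: ix.astype(str))
    return pd.DataFrame({"gene_id": hits.index, "adj_pvalue": hits.to_numpy()}).set_index(
        "gene_id"
    )


def sig_dc_gene_names(results, group_predictor: str | None = None, alpha: float = 0.05) -> list[str]:
    """Names-only variant of :func:`sig_dc_genes`."""
    return [str(g) for g in sig_dc_genes(results, group_predictor, alpha).index]


def extract(results, what: str, predictor: str = "all") -> pd.DataFrame:
    """Slice a result table: ``what`` in {adjpval, pval, coeff}, one or all predictors."""
    tables = {
        "adjpval": results.adj_pvalues,
        "pval": results.pvalues,
        "coeff": results.coefficients,
    }
    if what not in tables:
        raise ValueError(f"unknown selector {what!r}; choose from {sorted(tables)}")
    tab = tables[what]
    if tab is None:
        raise ValueError("adjusted p-values have not been computed yet")
    if predictor == "all":
        return tab.copy()
    _require_predictor(results, predictor)
    return tab[[predictor]].copy()
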