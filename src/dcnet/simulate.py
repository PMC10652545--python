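"""Two-group synthetic expression data with known differentially connected genes.

Each group's samples are drawn from a multivariate normal with a block
covariance: a "hub" block of genes shares a within-block correlation
(``base_rho`` in Group A, ``perturbed_rho`` in Group B) while the remaining
background genes are independent. When the two correlations differ, the hub
genes are differentially connected by construction and form the ground
truth. Under the negative-binomial count model the latent normals are
mapped through a Gaussian copula to negative-binomial quantiles, mimicking
overdispersed RNA-seq counts; because the mutual-information estimator is
rank-based, the latent correlation structure survives that margin
transform, so the simulator exercises exactly what the estimator sees.

The phenotype table carries the group label, one numeric covariate whose
mean may be shifted between groups (``confounding_strength``) and one
balanced categorical covariate. The ``covariate_driven_rho`` option makes
the hub correlation depend on the numeric covariate rather than (only) on
the group, which creates spurious group–connectivity differences exactly
when the covariate is confounded with the group — the situation covariate
adjustment exists to fix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from dcnet.io import PhenotypeTable

__all__ = ["SyntheticScenario", "simulate", "make_copd_like_fixture"]


@dataclass(frozen=True)
class SyntheticScenario:
    """Fully-seeded description of a two-group dataset.

    n_per_group : sample sizes of Group A and Group B.
    hub_size : number of genes in the perturbed block (gene ids g001..).
    base_rho / perturbed_rho : within-hub correlation in Group A / Group B.
    confounding_strength : mean shift of the numeric covariate in Group B
        (units of its SD ≈ 10).
    noise_sd : SD of independent measurement noise added to the
        unit-variance latent signal (default 0.1, so realised correlations
        track the nominal rho).
    count_model : "gaussian", or ("negbin", mu, size) for a Gaussian copula
        with negative-binomial margins.
    covariate_driven_rho : if True, a sample's hub correlation is
        perturbed_rho when its numeric covariate is above the population
        median and base_rho otherwise, in BOTH groups (connectivity is then
        driven by the covariate, not the condition).
    """

    n_per_group: tuple[int, int] = (60, 60)
    p: int = 30
    hub_size: int = 6
    base_rho: float = 0.2
    perturbed_rho: float = 0.7
    confounding_strength: float = 0.0
    noise_sd: float = 0.1
    count_model: str | tuple = "gaussian"
    covariate_driven_rho: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.hub_size > self.p:
            raise ValueError("hub_size cannot exceed the gene count")
        for rho in (self.base_rho, self.perturbed_rho):
            if not -1.0 / max(self.hub_size - 1, 1) < rho < 1.0:
                raise ValueError(
                    f"hub correlation {rho} gives a non-positive-definite "
                    f"covariance for block size {self.hub_size}"
                )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if min(self.n_per_group) < 4:
            raise ValueError("each group needs >= 4 samples")

    @property
    def gene_ids(self) -> list[str]:
        width = max(3, len(str(self.p)))
        return [f"g{k + 1:0{width}d}" for k in range(self.p)]

    @property
    def hub_genes(self) -> list[str]:
        return self.gene_ids[: self.hub_size]


def _hub_chol(hub_size: int, rho: float) -> np.ndarray:
    sigma = np.full((hub_size, hub_size), rho)
    np.fill_diagonal(sigma, 1.0)
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError("hub covariance is not positive definite") from exc


def _latent_group(
    rng: np.random.Generator,
    n: int,
    scenario: SyntheticScenario,
    rho: float,
    high_cov: np.ndarray | None,
) -> np.ndarray:
    """Latent unit-variance signal for one group; hub block equicorrelated."""
    p, h = scenario.p, scenario.hub_size
    z = rng.standard_normal((n, p))
    if h >= 2:
        if high_cov is None:
            z[:, :h] = z[:, :h] @ _hub_chol(h, rho).T
        else:
            lo = _hub_chol(h, scenario.base_rho).T
            hi = _hub_chol(h, scenario.perturbed_rho).T
            raw = z[:, :h]
            z[:, :h] = np.where(high_cov[:, None], raw @ hi, raw @ lo)
    return z


def simulate(scenario: SyntheticScenario) -> tuple[pd.DataFrame, PhenotypeTable, set]:
    """Draw one dataset; returns (expression, phenotype, truth DC gene ids)."""
    rng = np.random.default_rng(scenario.seed)
    n_a, n_b = scenario.n_per_group
    n = n_a + n_b
    sample_ids = [f"s{i + 1:04d}" for i in range(n)]
    group = np.array([0] * n_a + [1] * n_b)

    # numeric covariate, optionally mean-shifted in group B (confounding)
    covar = rng.normal(50.0, 10.0, size=n) + scenario.confounding_strength * group
    sexes = np.array(["F", "M"])[rng.integers(0, 2, size=n)]

    if scenario.covariate_driven_rho:
        high = covar > np.median(covar)
        za = _latent_group(rng, n_a, scenario, scenario.base_rho, high[:n_a])
        zb = _latent_group(rng, n_b, scenario, scenario.base_rho, high[n_a:])
    else:
        za = _latent_group(rng, n_a, scenario, scenario.base_rho, None)
        zb = _latent_group(rng, n_b, scenario, scenario.perturbed_rho, None)
    latent = np.vstack([za, zb])
    latent = latent + scenario.noise_sd * rng.standard_normal(latent.shape)

    if scenario.count_model == "gaussian":
        values = latent
    else:
        model, mu, size = scenario.count_model
        if model != "negbin":
            raise ValueError(f"unknown count model {scenario.count_model!r}")
        # Gaussian copula: latent normal -> uniform -> NB quantile
        u = stats.norm.cdf(latent / np.sqrt(1.0 + scenario.noise_sd**2))
        u = np.clip(u, 1e-12, 1.0 - 1e-12)
        prob = size / (size + mu)
        values = stats.nbinom.ppf(u, size, prob).astype(float)

    expr = pd.DataFrame(values, index=sample_ids, columns=scenario.gene_ids)
    pheno_df = pd.DataFrame(
        {
            "condition": group,
            "covar1": covar,
            "sex": sexes,
        },
        index=sample_ids,
    )
    pheno = PhenotypeTable(data=pheno_df, group_variable="condition")

    if scenario.covariate_driven_rho:
        truth: set = set()  # connectivity differences are covariate-, not group-driven
    elif scenario.base_rho != scenario.perturbed_rho:
        truth = set(scenario.hub_genes)
    else:
        truth = set()
    return expr, pheno, truth


def make_copd_like_fixture(seed: int = 0) -> tuple[pd.DataFrame, PhenotypeTable]:
    """Synthetic stand-in with the shape of a 406-sample × 28-gene COPD panel.

    Values are entirely synthetic (negative-binomial counts through a
    Gaussian copula); only the shape and the six phenotype variables —
    current smoking status (grouping), smoking pack years, age, gender,
    race, FEV1 percent — mirror the real panel, for documentation and smoke
    tests.
    """
    scenario = SyntheticScenario(
        n_per_group=(203, 203),
        p=28,
        hub_size=6,
        base_rho=0.2,
        perturbed_rho=0.6,
        count_model=("negbin", 100.0, 10.0),
        seed=seed,
    )
    expr, _, _ = simulate(scenario)
    n = expr.shape[0]
    rng = np.random.default_rng(seed + 1)
    group = np.array([0] * scenario.n_per_group[0] + [1] * scenario.n_per_group[1])
    pheno_df = pd.DataFrame(
        {
            "currentsmoking": group,
            "packyears": np.round(rng.gamma(2.0, 15.0, size=n), 1),
            "age": np.round(rng.normal(63.0, 8.0, size=n), 1),
            "gender": np.array(["F", "M"])[rng.integers(0, 2, size=n)],
            "race": np.array(["1", "2"])[rng.integers(0, 2, size=n)],
            "FEV1perc": np.round(rng.normal(65.0, 20.0, size=n), 1),
        },
        index=expr.index,
    )
    # Entrez-style opaque numeric gene ids
    gene_ids = [str(10000 + 7 * k) for k in range(scenario.p)]
    expr.columns = gene_ids
    return expr, PhenotypeTable(data=pheno_df, group_variable="currentsmoking")
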