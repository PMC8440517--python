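"""Biometrical path models linking conditional and unconditional SNP effects.

A standard GWAS regresses a phenotype on one person's genotype, so the
marginal ("unconditional") slope mixes the direct effect of that genotype
with indirect effects of relatives' genotypes through parent-offspring
genotype correlation (0.5 under additive transmission without assortment).
Each model here is summarised by a coefficient matrix ``A`` with

    E[beta_unconditional] = A @ theta_conditional,

so the conditional effects are recovered as ``A^{-1} @ beta`` for
just-identified designs.  The two shipped models:

birthweight
    Two GWAS of the same phenotype on different genotypes: a person's own
    birth weight on their own genotype (direct effect ``o`` plus half the
    maternal effect ``m``) and their first child's birth weight on the
    person's genotype (maternal effect plus half the direct effect), giving
    ``A = [[1, 0.5], [0.5, 1]]``.

fertility3 (and its two-trait reduction fertility2)
    Family-size GWAS: children mothered on the mother's genotype (female
    effect ``f`` plus half the sibling-specific effect ``s``), children
    fathered on the father's genotype, and number of siblings on the
    offspring's genotype (half of each parental effect plus ``s``).

The module also carries the model-implied covariance algebra used by the
multi-group SEM over (genotype, own phenotype, offspring phenotype), derived
from identity-by-descent relatedness coefficients (parent-offspring 0.5,
grandmother-grandchild 0.25).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .sumstats_io import ConfigurationError

__all__ = [
    "PathModelSpec",
    "ImpliedCovariance",
    "birthweight_model",
    "fertility2_model",
    "fertility_model",
    "get_model",
    "load_model_config",
    "conditional_from_unconditional",
    "implied_sigma",
    "MODEL_REGISTRY",
]


@dataclass(frozen=True)
class PathModelSpec:
    """Coefficient matrix mapping conditional effects to GWAS expectations.

    ``A[i, j]`` is the relatedness weight with which conditional effect j
    appears in unconditional GWAS i; diagonals are 1 (each GWAS tags its own
    effect fully) and off-diagonals lie in [0, 1].
    """

    labels: tuple[str, ...]
    A: np.ndarray
    relatedness: float = 0.5
    free_residuals: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        object.__setattr__(self, "A", A)
        k = len(self.labels)
        if A.shape != (k, k):
            raise ConfigurationError("A must be square and match labels")
        if not np.allclose(np.diag(A), 1.0):
            raise ConfigurationError("diagonal of A must be 1")
        off = A[~np.eye(k, dtype=bool)]
        if np.any((off < 0) | (off > 1)):
            raise ConfigurationError("off-diagonals of A must lie in [0, 1]")
        if abs(np.linalg.det(A)) < 1e-12:
            raise ConfigurationError("A must be invertible")

    @property
    def k(self) -> int:
        return len(self.labels)

    @property
    def a_inv(self) -> np.ndarray:
        return np.linalg.inv(self.A)


@dataclass
class ImpliedCovariance:
    """Model-implied covariance matrix for one observation group."""

    sigma: np.ndarray
    variables: tuple[str, ...]
    group: str


def birthweight_model() -> PathModelSpec:
    """Two-trait maternal/offspring model for own and offspring birth weight.

    E[beta_own] = o + 0.5 m and E[beta_offspring] = m + 0.5 o, i.e.
    A = [[1, 0.5], [0.5, 1]] over labels (offspring, maternal).
    """
    return PathModelSpec(
        labels=("offspring", "maternal"),
        A=np.array([[1.0, 0.5], [0.5, 1.0]]),
        free_residuals=("sigma1_sq", "sigma2_sq", "c"),
    )


def fertility2_model() -> PathModelSpec:
    """Female + sibling-specific effects from children-mothered and sibling GWAS."""
    return PathModelSpec(
        labels=("female", "sibling"),
        A=np.array([[1.0, 0.5], [0.5, 1.0]]),
    )


def fertility_model() -> PathModelSpec:
    """Female, male and sibling-specific fertility effects.

    Children mothered tags f + 0.5 s, children fathered tags m + 0.5 s and
    number of siblings tags 0.5 f + 0.5 m + s.
    """
    return PathModelSpec(
        labels=("female", "male", "sibling"),
        A=np.array(
            [
                [1.0, 0.0, 0.5],
                [0.0, 1.0, 0.5],
                [0.5, 0.5, 1.0],
            ]
        ),
    )


MODEL_REGISTRY = {
    "birthweight": birthweight_model,
    "fertility2": fertility2_model,
    "fertility3": fertility_model,
}


def get_model(name: str) -> PathModelSpec:
    try:
        return MODEL_REGISTRY[name]()
    except KeyError:
        raise ConfigurationError(
            f"unknown model {name!r}; available: {sorted(MODEL_REGISTRY)}"
        ) from None


def load_model_config(path) -> PathModelSpec:
    """Load a custom model (labels + A matrix) from a YAML config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    try:
        labels = tuple(cfg["labels"])
        A = np.asarray(cfg["A"], dtype=float)
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"model config needs 'labels' and 'A': {exc}") from exc
    return PathModelSpec(labels=labels, A=A)


def conditional_from_unconditional(beta_unadj, model: PathModelSpec) -> np.ndarray:
    """Invert the relatedness mixing: theta = A^{-1} beta.

    ``beta_unadj`` may be a K-vector or an (n, K) array of per-variant
    unconditional GWAS slopes, ordered as ``model.labels``.
    """
    beta = np.asarray(beta_unadj, dtype=float)
    return np.linalg.solve(model.A, beta.T).T


def implied_sigma(theta, q: float, group: str = "both") -> ImpliedCovariance:
    """Model-implied covariance for the birth weight SEM groups.

    Parameters
    ----------
    theta
        Structural parameters ``(o, m, sigma1_sq, sigma2_sq, c)``: direct and
        maternal genetic effects, residual variances of own and offspring
        phenotype and their residual covariance.
    q
        Genotype variance ``2 p (1 - p)`` at the variant.
    group
        ``"own"`` for individuals observed with their own phenotype only
        (variables G, Y1), ``"offspring"`` for those with the offspring
        phenotype only (G, Y2), ``"both"`` for the 3x3 group (G, Y1, Y2).

    The algebra follows from Y1 = o G + m G_mother + e1 and
    Y2 = o G_child + m G + e2 with Cov(G, G_mother) = Cov(G, G_child) = q/2
    and Cov(G_mother, G_child) = q/4 (grandmother-grandchild).
    """
    o, m, s1, s2, c = (float(x) for x in theta)
    if q <= 0:
        raise ConfigurationError("genotype variance q must be positive")
    gvar = q * (o * o + m * m + o * m)
    cov_g_y1 = (o + 0.5 * m) * q
    cov_g_y2 = (m + 0.5 * o) * q
    if group == "own":
        sigma = np.array([[q, cov_g_y1], [cov_g_y1, gvar + s1]])
        return ImpliedCovariance(sigma, ("G", "Y1"), group)
    if group == "offspring":
        sigma = np.array([[q, cov_g_y2], [cov_g_y2, gvar + s2]])
        return ImpliedCovariance(sigma, ("G", "Y2"), group)
    if group == "both":
        cov_y1_y2 = 0.5 * q * (o * o + m * m) + 1.25 * o * m * q + c
        sigma = np.array(
            [
                [q, cov_g_y1, cov_g_y2],
                [cov_g_y1, gvar + s1, cov_y1_y2],
                [cov_g_y2, cov_y1_y2, gvar + s2],
            ]
        )
        return ImpliedCovariance(sigma, ("G", "Y1", "Y2"), group)
    raise ConfigurationError(f"unknown group {group!r}")
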