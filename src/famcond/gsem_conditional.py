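"""Per-variant conditional effects with overlap-aware sampling covariance.

This estimator follows the two-stage logic of genomic structural equation
modelling.  Stage one runs bivariate LD score regression on every pair of
input GWAS; the cross-trait intercepts c_ij estimate the correlation between
the estimation errors of the same variant's betas across GWAS, which is what
shared samples induce.  Stage two solves, per variant, the just-identified
path model theta = A^{-1} beta with sampling covariance

    Cov(theta_hat) = A^{-1} V A^{-T},   V_ii = se_i^2,  V_ij = c_ij se_i se_j.

For just-identified models this closed form coincides with the diagonally
weighted least squares solution, so no iterative SEM engine is needed; the
module restricts itself to such models.  With c = I (no overlap) the result
reduces exactly to the linear approximation.  Intercepts are clamped to
+/- 0.99 before building V so that V stays positive definite; a non-PD V
(possible with user-supplied c) is repaired by eigenvalue clipping with a
warning.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import ldsc
from .linear_approx import ConditionalEstimate, wald_log10p, wald_p
from .path_models import PathModelSpec
from .sumstats_io import ConfigurationError, HarmonizedSet, InputError, LDScorePanel

__all__ = [
    "SamplingCovariance",
    "estimate_intercept_matrix",
    "build_sampling_covariance",
    "conditional_solve",
    "conditional_gwas",
]

INTERCEPT_CLAMP = 0.99


def estimate_intercept_matrix(
    tables: HarmonizedSet, ld: LDScorePanel, n_blocks: int | None = None
) -> np.ndarray:
    """K x K matrix of cross-trait LDSC intercepts (diagonal 1).

    z-scores are beta/se from each harmonized table; off-diagonals are
    clamped into [-1, 1] (an error correlation cannot exceed 1).
    """
    k = len(tables.tables)
    if k < 2:
        raise ConfigurationError("need at least two tables for an intercept matrix")
    merged = tables.tables[0].records.merge(
        ld.records[["variant_id", "ld_score"]], on="variant_id", how="inner"
    )
    if merged.empty:
        raise InputError("no variants shared between sumstats and LD-score panel")
    keep = tables.tables[0].records["variant_id"].isin(set(merged["variant_id"]))
    keep = keep.to_numpy()

    zs, ns = [], []
    for t in tables.tables:
        rec = t.records.loc[keep]
        zs.append((rec["beta"] / rec["se"]).to_numpy(float))
        ns.append(float(rec["n"].median()))
    panel = ld.records.set_index("variant_id")["ld_score"]
    scores = panel.loc[tables.tables[0].records.loc[keep, "variant_id"]].to_numpy(float)

    c = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            est = ldsc.cross_trait_intercept(
                zs[i], zs[j], scores, ns[i], ns[j], n_blocks=n_blocks, m=ld.m
            )
            c[i, j] = c[j, i] = float(np.clip(est.intercept, -1.0, 1.0))
    return c


class SamplingCovariance:
    """Per-variant K x K sampling covariance V from SEs and intercepts."""

    def __init__(self, se_vec, c):
        se = np.asarray(se_vec, dtype=float)
        c = np.asarray(c, dtype=float)
        if np.any(se <= 0):
            raise InputError("standard errors must be positive")
        c = c.copy()
        off = ~np.eye(len(se), dtype=bool)
        c[off] = np.clip(c[off], -INTERCEPT_CLAMP, INTERCEPT_CLAMP)
        np.fill_diagonal(c, 1.0)
        v = c * np.outer(se, se)
        eigval, eigvec = np.linalg.eigh(v)
        if eigval.min() <= 0:
            warnings.warn(
                "sampling covariance not positive definite; repairing by "
                "eigenvalue clipping",
                stacklevel=2,
            )
            floor = 1e-8 * eigval.max()
            v = (eigvec * np.maximum(eigval, floor)) @ eigvec.T
        self.c = c
        self.v = v


def build_sampling_covariance(se_vec, c) -> SamplingCovariance:
    return SamplingCovariance(se_vec, c)


def conditional_solve(
    beta_vec, se_vec, c, model: PathModelSpec, variant_id: str = ""
) -> ConditionalEstimate:
    """Closed-form conditional effects for one variant.

    theta = A^{-1} beta, Cov = A^{-1} V A^{-T}; the point estimate does not
    depend on V, only the uncertainty does.  Exactly the DWLS solution for a
    just-identified model.
    """
    beta = np.asarray(beta_vec, dtype=float)
    if len(beta) != model.k:
        raise ConfigurationError(
            f"model {model.labels} expects {model.k} GWAS, got {len(beta)}"
        )
    samp = SamplingCovariance(se_vec, c)
    a_inv = model.a_inv
    theta = a_inv @ beta
    cov = a_inv @ samp.v @ a_inv.T
    se = np.sqrt(np.diag(cov))
    return ConditionalEstimate(
        variant_id=variant_id,
        labels=model.labels,
        beta_adj=theta,
        cov_adj=cov,
        wald_p=wald_p(theta, se),
        log10_p=wald_log10p(theta, se),
        method_tag="gsem",
    )


def conditional_gwas(
    tables: HarmonizedSet,
    model: PathModelSpec,
    ld: LDScorePanel | None = None,
    intercept_matrix: np.ndarray | None = None,
) -> pd.DataFrame:
    """Conditional GWAS over all harmonized variants.

    The intercept matrix is estimated once genome-wide (stage one) unless
    supplied, then the per-variant closed-form solve is applied (stage two).
    Output is deterministic and invariant to partitioning of the table.
    """
    k = len(tables.tables)
    if k != model.k:
        raise ConfigurationError(
            f"model {model.labels} expects {model.k} GWAS, got {k} tables"
        )
    if intercept_matrix is None:
        if ld is None:
            raise ConfigurationError("need an LD-score panel or an intercept matrix")
        intercept_matrix = estimate_intercept_matrix(tables, ld)
    c = np.asarray(intercept_matrix, dtype=float)
    off = ~np.eye(k, dtype=bool)
    c = c.copy()
    c[off] = np.clip(c[off], -INTERCEPT_CLAMP, INTERCEPT_CLAMP)
    np.fill_diagonal(c, 1.0)

    beta = np.column_stack([t.records["beta"].to_numpy(float) for t in tables.tables])
    se = np.column_stack([t.records["se"].to_numpy(float) for t in tables.tables])
    a_inv = model.a_inv
    theta = beta @ a_inv.T
    # cov_v = A^{-1} (c * se se^T)_v A^{-T} for each variant v
    cov = np.einsum("ik,jl,kl,vk,vl->vij", a_inv, a_inv, c, se, se, optimize=True)
    se_adj = np.sqrt(np.diagonal(cov, axis1=1, axis2=2))

    ref = tables.tables[0].records
    out = pd.DataFrame(
        {
            "variant_id": ref["variant_id"].to_numpy(),
            "chrom": ref["chrom"].to_numpy(),
            "pos": ref["pos"].to_numpy(),
            "effect_allele": ref["effect_allele"].to_numpy(),
            "other_allele": ref["other_allele"].to_numpy(),
            "eaf": ref["eaf"].to_numpy(float),
        }
    )
    for a, label in enumerate(model.labels):
        out[f"beta_{label}"] = theta[:, a]
        out[f"se_{label}"] = se_adj[:, a]
        out[f"p_{label}"] = wald_p(theta[:, a], se_adj[:, a])
        out[f"log10p_{label}"] = wald_log10p(theta[:, a], se_adj[:, a])
    for a in range(k):
        for b in range(a + 1, k):
            out[f"cov_{model.labels[a]}_{model.labels[b]}"] = cov[:, a, b]
    return out
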