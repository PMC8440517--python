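"""Closed-form conditional maternal/offspring effects from two GWAS.

Given unadjusted slopes from a GWAS of own phenotype (expectation o + m/2)
and a GWAS of offspring phenotype on the same genotype (expectation m + o/2),
the conditional effects follow by inverting the 2x2 relatedness matrix:

    beta_o_adj = -2/3 beta_m_unadj + 4/3 beta_o_unadj
    beta_m_adj =  4/3 beta_m_unadj - 2/3 beta_o_unadj

with standard errors

    SE(beta_o_adj) = sqrt(4/9 se_m^2 + 16/9 se_o^2)
    SE(beta_m_adj) = sqrt(16/9 se_m^2 + 4/9 se_o^2)

and estimate covariance -8/9 (se_m^2 + se_o^2).  The transformation assumes
the two GWAS share no samples; with overlap the reported standard errors are
conservative (they omit a negative covariance term) and the Wald tests
deflate.  Two-sided Wald p-values are computed on the normal scale, with
log10 p available to avoid underflow in extreme signals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .path_models import birthweight_model
from .sumstats_io import ConfigurationError, HarmonizedSet, InputError

__all__ = ["ConditionalEstimate", "adjust_pair", "adjust_table", "wald_p", "wald_log10p"]

_LOG10E = np.log10(np.e)


def wald_p(beta, se):
    """Two-sided normal Wald p-value; p = 1 at beta = 0."""
    z = np.abs(np.asarray(beta, float)) / np.asarray(se, float)
    return 2.0 * stats.norm.sf(z)


def wald_log10p(beta, se):
    """log10 of the two-sided Wald p-value, stable below float underflow."""
    z = np.abs(np.asarray(beta, float)) / np.asarray(se, float)
    return (stats.norm.logsf(z) + np.log(2.0)) * _LOG10E


@dataclass
class ConditionalEstimate:
    """Per-variant conditional effect vector with covariance and Wald tests."""

    variant_id: str
    labels: tuple[str, ...]
    beta_adj: np.ndarray
    cov_adj: np.ndarray
    wald_p: np.ndarray
    method_tag: str
    log10_p: np.ndarray | None = None

    @property
    def se_adj(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_adj))


def adjust_pair(
    beta_m_unadj: float,
    beta_o_unadj: float,
    se_m: float,
    se_o: float,
    variant_id: str = "",
) -> ConditionalEstimate:
    """Conditional (offspring, maternal) effects for one variant.

    ``beta_o_unadj``/``se_o`` come from the GWAS of own phenotype and
    ``beta_m_unadj``/``se_m`` from the GWAS of offspring phenotype (the
    unadjusted maternal signal).
    """
    vals = np.array([beta_m_unadj, beta_o_unadj, se_m, se_o], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise InputError("adjust_pair requires finite inputs")
    if se_m <= 0 or se_o <= 0:
        raise InputError("standard errors must be positive")
    model = birthweight_model()
    a_inv = model.a_inv
    beta_unadj = np.array([beta_o_unadj, beta_m_unadj])
    beta_adj = a_inv @ beta_unadj
    cov = a_inv @ np.diag([se_o**2, se_m**2]) @ a_inv.T
    se = np.sqrt(np.diag(cov))
    return ConditionalEstimate(
        variant_id=variant_id,
        labels=model.labels,
        beta_adj=beta_adj,
        cov_adj=cov,
        wald_p=wald_p(beta_adj, se),
        log10_p=wald_log10p(beta_adj, se),
        method_tag="linear_approx",
    )


def adjust_table(pair: HarmonizedSet) -> pd.DataFrame:
    """Apply the linear transformation to every harmonized variant.

    ``pair`` must hold exactly two tables: first the GWAS of own phenotype,
    second the GWAS of offspring phenotype.  Returns one row per variant with
    conditional betas, SEs, the offspring-maternal estimate covariance and
    two-sided Wald p-values; output is deterministic given input order.
    """
    if len(pair.tables) != 2:
        raise ConfigurationError(
            f"adjust_table needs exactly two harmonized tables, got {len(pair.tables)}"
        )
    own, off = pair.tables[0].records, pair.tables[1].records
    model = birthweight_model()
    a_inv = model.a_inv
    beta_u = np.column_stack([own["beta"].to_numpy(float), off["beta"].to_numpy(float)])
    var_u = np.column_stack(
        [own["se"].to_numpy(float) ** 2, off["se"].to_numpy(float) ** 2]
    )
    beta_adj = beta_u @ a_inv.T
    var_adj = var_u @ (a_inv**2).T
    se_adj = np.sqrt(var_adj)
    cov_om = (a_inv[0] * a_inv[1]) @ var_u.T
    out = pd.DataFrame(
        {
            "variant_id": own["variant_id"].to_numpy(),
            "chrom": own["chrom"].to_numpy(),
            "pos": own["pos"].to_numpy(),
            "effect_allele": own["effect_allele"].to_numpy(),
            "other_allele": own["other_allele"].to_numpy(),
            "eaf": own["eaf"].to_numpy(float),
        }
    )
    for k, label in enumerate(model.labels):
        out[f"beta_{label}"] = beta_adj[:, k]
        out[f"se_{label}"] = se_adj[:, k]
        out[f"p_{label}"] = wald_p(beta_adj[:, k], se_adj[:, k])
        out[f"log10p_{label}"] = wald_log10p(beta_adj[:, k], se_adj[:, k])
    out["cov_offspring_maternal"] = cov_om
    out["n_own"] = own["n"].to_numpy()
    out["n_offspring"] = off["n"].to_numpy()
    return out
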