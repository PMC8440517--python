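"""LD score regression: intercepts, sample overlap and genetic correlation.

Univariate LD score regression fits E[z_j^2] = a + h2 * n * l_j / M over
variants j with LD score l_j, total variant count M and GWAS size n; the
intercept a is 1 in a well-calibrated GWAS and inflates under confounding.
The bivariate version regresses z1_j * z2_j on sqrt(n1 n2) * l_j / M; its
intercept equals N_s * r_p / sqrt(n1 n2) where N_s is the number of samples
shared by the two GWAS and r_p the phenotypic correlation, which makes it a
summary-statistics-only estimator of sample overlap:

    N_s = intercept * sqrt(n1 n2) / r_p.

Regressions are weighted in two steps: a first pass with 1/max(l, 1)
heteroskedasticity weights, then a second pass with weights proportional to
the inverse conditional variance of the regressand implied by the first-pass
fit.  Standard errors come from a delete-one block jackknife over
position-contiguous blocks (200 blocks by default, floor(n_snps / 50) for
small panels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sumstats_io import InputError, LDScorePanel

__all__ = [
    "InterceptEstimate",
    "OverlapEstimate",
    "GeneticCorrelation",
    "univariate_intercept",
    "cross_trait_intercept",
    "overlap_from_intercept",
    "intercept_from_overlap",
    "genetic_correlation",
]

DEFAULT_N_BLOCKS = 200
MIN_SNPS = 200
_EXPECTED_FLOOR = 0.05  # floor on fitted expectations when building weights


@dataclass
class InterceptEstimate:
    """Intercept and slope of an LD score regression with jackknife SEs."""

    intercept: float
    intercept_se: float
    slope: float
    slope_se: float
    n_blocks: int
    n_snps_used: int


@dataclass
class OverlapEstimate:
    """Sample overlap implied by a cross-trait intercept.

    ``n_overlap`` is clamped to [0, min(n1, n2)]; the unclamped value is kept
    in ``raw_n_overlap``.  Rounding to whole individuals is left to the
    reporting layer.
    """

    n_overlap: float
    intercept_used: float
    n1: int
    n2: int
    r_pheno: float
    raw_n_overlap: float


@dataclass
class GeneticCorrelation:
    rg: float
    rg_se: float
    h2_1: float
    h2_2: float
    gcov_intercept: float
    out_of_range: bool = False
    status: str = "ok"


def _resolve_panel(ld, m=None):
    """Accept an LDScorePanel or a bare array of LD scores."""
    if isinstance(ld, LDScorePanel):
        scores = ld.records["ld_score"].to_numpy(float)
        weights = (
            ld.records["weight"].to_numpy(float)
            if "weight" in ld.records.columns
            else None
        )
        return scores, weights, ld.m
    scores = np.asarray(ld, dtype=float)
    return scores, None, (int(m) if m is not None else len(scores))


def _n_blocks_for(n_snps: int, n_blocks: int | None) -> int:
    if n_blocks is None:
        n_blocks = min(DEFAULT_N_BLOCKS, max(2, n_snps // 50))
    if n_snps <= n_blocks:
        raise InputError(f"{n_snps} variants cannot fill {n_blocks} jackknife blocks")
    return int(n_blocks)


def _wls_jackknife(y, x, w, n_blocks):
    """Weighted regression of y on [1, x] with delete-one-block jackknife.

    Returns full-sample (intercept, slope), their jackknife SEs, and the
    (n_blocks, 2) array of delete-one estimates for composite statistics.
    """
    n = len(y)
    block_id = np.minimum((np.arange(n) * n_blocks) // n, n_blocks - 1)
    # per-block moment sums for X'WX and X'Wy with X = [1, x]
    sw = np.bincount(block_id, weights=w, minlength=n_blocks)
    swx = np.bincount(block_id, weights=w * x, minlength=n_blocks)
    swxx = np.bincount(block_id, weights=w * x * x, minlength=n_blocks)
    swy = np.bincount(block_id, weights=w * y, minlength=n_blocks)
    swxy = np.bincount(block_id, weights=w * x * y, minlength=n_blocks)

    def _solve(a, b, c, d, e):
        # [[a, b], [b, c]] @ (int, slope) = (d, e)
        det = a * c - b * b
        return np.stack([(c * d - b * e) / det, (a * e - b * d) / det], axis=-1)

    full = _solve(sw.sum(), swx.sum(), swxx.sum(), swy.sum(), swxy.sum())
    deletes = _solve(
        sw.sum() - sw,
        swx.sum() - swx,
        swxx.sum() - swxx,
        swy.sum() - swy,
        swxy.sum() - swxy,
    )
    b = n_blocks
    se = np.sqrt((b - 1) / b * np.sum((deletes - deletes.mean(axis=0)) ** 2, axis=0))
    return full, se, deletes


def _check_alignment(*arrays):
    lengths = {len(a) for a in arrays}
    if len(lengths) != 1:
        raise InputError("z-scores and LD scores must be aligned on the same variants")
    n = lengths.pop()
    if n < MIN_SNPS:
        raise InputError(f"LD score regression needs >= {MIN_SNPS} variants, got {n}")
    return n


def _univariate_fit(z, scores, lweights, x, n_blocks):
    """Two-step weighted fit of z^2 on x; returns fit tuple and weights."""
    y = z * z
    base = 1.0 / np.maximum(scores, 1.0) if lweights is None else lweights
    (a0, b0), _, _ = _wls_jackknife(y, x, base, n_blocks)
    expected = np.maximum(a0 + b0 * x, _EXPECTED_FLOOR)
    w = base / (2.0 * expected**2)
    return _wls_jackknife(y, x, w, n_blocks), expected


def univariate_intercept(z, ld, n, n_blocks: int | None = None, m=None) -> InterceptEstimate:
    """Intercept and heritability slope of one GWAS's chi-square statistics.

    ``z`` are per-variant z-scores aligned with the LD scores in ``ld`` (an
    LDScorePanel, or an array with the genome-wide count passed as ``m``);
    ``n`` is the GWAS sample size (scalar or per-variant).
    """
    z = np.asarray(z, dtype=float)
    scores, lweights, m_tot = _resolve_panel(ld, m)
    n_snps = _check_alignment(z, scores)
    n_blocks = _n_blocks_for(n_snps, n_blocks)
    x = np.asarray(n, dtype=float) * scores / m_tot
    ((a, b), (a_se, b_se), _), _ = _univariate_fit(z, scores, lweights, x, n_blocks)
    return InterceptEstimate(a, a_se, b, b_se, n_blocks, n_snps)


def cross_trait_intercept(
    z1, z2, ld, n1, n2, n_blocks: int | None = None, m=None
) -> InterceptEstimate:
    """Bivariate LD score regression of z1*z2 on sqrt(n1 n2) * l / M.

    The intercept estimates N_s * r_p / sqrt(n1 n2); the slope estimates the
    genetic covariance.  Symmetric in the two traits.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    scores, lweights, m_tot = _resolve_panel(ld, m)
    n_snps = _check_alignment(z1, z2, scores)
    n_blocks = _n_blocks_for(n_snps, n_blocks)

    x1 = np.asarray(n1, dtype=float) * scores / m_tot
    x2 = np.asarray(n2, dtype=float) * scores / m_tot
    _, e1 = _univariate_fit(z1, scores, lweights, x1, n_blocks)
    _, e2 = _univariate_fit(z2, scores, lweights, x2, n_blocks)

    y = z1 * z2
    x = np.sqrt(np.asarray(n1, float) * np.asarray(n2, float)) * scores / m_tot
    base = 1.0 / np.maximum(scores, 1.0) if lweights is None else lweights
    (a0, b0), _, _ = _wls_jackknife(y, x, base, n_blocks)
    e12 = a0 + b0 * x
    w = base / np.maximum(e1 * e2 + e12**2, _EXPECTED_FLOOR)
    (a, b), (a_se, b_se), _ = _wls_jackknife(y, x, w, n_blocks)
    return InterceptEstimate(a, a_se, b, b_se, n_blocks, n_snps)


def overlap_from_intercept(intercept: float, n1: int, n2: int, r_pheno: float) -> OverlapEstimate:
    """Convert a cross-trait intercept into an estimated number of shared samples.

    N_s = intercept * sqrt(n1 n2) / r_pheno, clamped to [0, min(n1, n2)];
    negative raw estimates (possible under sampling noise) clamp to 0.
    """
    if r_pheno == 0:
        raise InputError("overlap is undefined for r_pheno = 0")
    if n1 <= 0 or n2 <= 0:
        raise InputError("sample sizes must be positive")
    raw = intercept * np.sqrt(float(n1) * float(n2)) / r_pheno
    clamped = float(np.clip(raw, 0.0, min(n1, n2)))
    return OverlapEstimate(
        n_overlap=clamped,
        intercept_used=float(intercept),
        n1=int(n1),
        n2=int(n2),
        r_pheno=float(r_pheno),
        raw_n_overlap=float(raw),
    )


def intercept_from_overlap(n_overlap: float, n1: int, n2: int, r_pheno: float) -> float:
    """Expected cross-trait intercept for a known overlap: N_s r_p / sqrt(n1 n2)."""
    if not 0 <= n_overlap <= min(n1, n2):
        raise InputError("n_overlap must lie in [0, min(n1, n2)]")
    return float(n_overlap) * float(r_pheno) / np.sqrt(float(n1) * float(n2))


def genetic_correlation(z1, z2, ld, n1, n2, n_blocks: int | None = None, m=None) -> GeneticCorrelation:
    """Genetic correlation rg = gcov / sqrt(h2_1 h2_2) with jackknife SE.

    Heritabilities are the univariate slopes and the genetic covariance the
    bivariate slope of the LD score regressions; the SE comes from a block
    jackknife of the ratio (shared blocks across the three regressions).  A
    nonpositive heritability estimate leaves rg undefined (NaN, status
    ``"nonpositive_h2"``); estimates outside [-1, 1] are reported with
    ``out_of_range`` set rather than truncated.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    scores, lweights, m_tot = _resolve_panel(ld, m)
    n_snps = _check_alignment(z1, z2, scores)
    n_blocks = _n_blocks_for(n_snps, n_blocks)

    x1 = np.asarray(n1, float) * scores / m_tot
    x2 = np.asarray(n2, float) * scores / m_tot
    x12 = np.sqrt(np.asarray(n1, float) * np.asarray(n2, float)) * scores / m_tot

    (fit1, se1_, del1), e1 = _univariate_fit(z1, scores, lweights, x1, n_blocks)
    (fit2, se2_, del2), e2 = _univariate_fit(z2, scores, lweights, x2, n_blocks)

    y = z1 * z2
    base = 1.0 / np.maximum(scores, 1.0) if lweights is None else lweights
    (a0, b0), _, _ = _wls_jackknife(y, x12, base, n_blocks)
    e12 = a0 + b0 * x12
    w = base / np.maximum(e1 * e2 + e12**2, _EXPECTED_FLOOR)
    fit12, _, del12 = _wls_jackknife(y, x12, w, n_blocks)

    h2_1, h2_2, gcov = fit1[1], fit2[1], fit12[1]
    if h2_1 <= 0 or h2_2 <= 0:
        return GeneticCorrelation(
            rg=np.nan,
            rg_se=np.nan,
            h2_1=h2_1,
            h2_2=h2_2,
            gcov_intercept=fit12[0],
            status="nonpositive_h2",
        )
    rg = gcov / np.sqrt(h2_1 * h2_2)
    prod = del1[:, 1] * del2[:, 1]
    valid = prod > 0
    rg_del = np.full(n_blocks, np.nan)
    rg_del[valid] = del12[valid, 1] / np.sqrt(prod[valid])
    nb = int(valid.sum())
    if nb >= 2:
        rd = rg_del[valid]
        rg_se = float(np.sqrt((nb - 1) / nb * np.sum((rd - rd.mean()) ** 2)))
    else:
        rg_se = np.nan
    return GeneticCorrelation(
        rg=float(rg),
        rg_se=rg_se,
        h2_1=float(h2_1),
        h2_2=float(h2_2),
        gcov_intercept=float(fit12[0]),
        out_of_range=bool(abs(rg) > 1),
    )
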