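"""Multi-group maximum-likelihood SEM on covariances built from summary stats.

For one variant, observed covariance matrices are reconstructed from the two
unadjusted GWAS using the allele frequency, beta, phenotype variance and
sample size, under the assumption that frequency, beta and variance are the
same in three groups that differ only in which phenotypes they observe:
own phenotype only (G, Y1), offspring phenotype only (G, Y2), and both
(G, Y1, Y2).  The both-group size is the (estimated) sample overlap; its
Y1-Y2 covariance is filled in from the phenotypic correlation.  The
structural model (direct effect o, maternal effect m, residual variances
sigma1^2, sigma2^2 and residual covariance c -- c is free only when the
both-phenotypes group is non-empty) is fit by minimising the multi-group
Wishart ML discrepancy

    F(theta) = sum_g (N_g - 1) [ ln|Sigma_g| + tr(S_g Sigma_g^{-1})
                                 - ln|S_g| - p_g ],

which is -2 log-likelihood up to a constant, so the estimate covariance is
the inverse Hessian of F/2 at the optimum (observed information, computed by
central differences with parameter-scaled steps).

Because the model is just-identified for the cross-covariances, covariance
sets built under the consistency assumption admit an exact analytic optimum
with F = 0; the fitter starts there (falling back to jittered quasi-Newton
restarts on a log-variance scale when the analytic candidate is infeasible),
and the table driver exploits it to process whole GWAS panels with a single
vectorised Hessian pass per variant batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .linear_approx import wald_log10p, wald_p
from .path_models import PathModelSpec, birthweight_model, implied_sigma
from .sumstats_io import ConfigurationError, HarmonizedSet, InputError

__all__ = [
    "CovGroup",
    "GroupCovarianceSet",
    "SemFit",
    "build_group_covariances",
    "discrepancy",
    "fit_ml",
    "sem_adjust_table",
]

PARAM_LABELS = ("o", "m", "sigma1_sq", "sigma2_sq", "c")
_PENALTY = 1e10
_F_TOL = 1e-8  # relative change convergence tolerance
_MAX_RESTARTS = 5


@dataclass
class CovGroup:
    name: str  # "own" | "offspring" | "both"
    s: np.ndarray
    n: float


@dataclass
class GroupCovarianceSet:
    """Observed covariance matrices for the three observation groups."""

    q: float
    r_pheno: float | None
    groups: list[CovGroup]

    def __post_init__(self) -> None:
        if not 0 < self.q <= 0.5:
            raise InputError("genotype variance q must lie in (0, 0.5]")
        for g in self.groups:
            if g.n < 0:
                raise InputError("group sample sizes must be nonnegative")
            if not np.allclose(g.s, g.s.T):
                raise InputError(f"observed covariance for group {g.name!r} not symmetric")

    @property
    def n_both(self) -> float:
        return sum(g.n for g in self.groups if g.name == "both")


@dataclass
class SemFit:
    """Fitted structural parameters for one variant."""

    variant_id: str
    labels: tuple[str, str]
    theta: np.ndarray  # (o, m, sigma1_sq, sigma2_sq, c)
    se: np.ndarray
    cov_theta: np.ndarray
    f_min: float
    converged: bool
    c_free: bool
    wald_p: np.ndarray  # for (o, m)
    n_restarts: int = 0

    @property
    def beta_adj(self) -> np.ndarray:
        return self.theta[:2]


def build_group_covariances(
    beta_own: float,
    beta_off: float,
    eaf: float,
    r_pheno: float,
    n_own_only: float,
    n_off_only: float,
    n_both: float,
    var_y1: float = 1.0,
    var_y2: float = 1.0,
) -> GroupCovarianceSet:
    """Observed covariance matrices for one variant from summary statistics.

    The own-only group covers (G, Y1) with Cov(G, Y1) = beta_own * q, the
    offspring-only group (G, Y2) analogously, and the both group is 3x3 with
    Cov(Y1, Y2) = r_pheno * sqrt(var_y1 * var_y2).
    """
    if not 0 < eaf < 1:
        raise InputError("allele frequency must lie in (0, 1)")
    if var_y1 <= 0 or var_y2 <= 0:
        raise InputError("phenotype variances must be positive")
    q = 2.0 * eaf * (1.0 - eaf)
    c1 = beta_own * q
    c2 = beta_off * q
    s_own = np.array([[q, c1], [c1, var_y1]])
    s_off = np.array([[q, c2], [c2, var_y2]])
    groups = [CovGroup("own", s_own, n_own_only), CovGroup("offspring", s_off, n_off_only)]
    if n_both > 0:
        c12 = r_pheno * np.sqrt(var_y1 * var_y2)
        s_both = np.array([[q, c1, c2], [c1, var_y1, c12], [c2, c12, var_y2]])
        groups.append(CovGroup("both", s_both, n_both))
    return GroupCovarianceSet(q=q, r_pheno=r_pheno, groups=groups)


def discrepancy(theta, covset: GroupCovarianceSet) -> float:
    """Multi-group Wishart ML discrepancy F(theta); >= 0, 0 iff exact fit."""
    total = 0.0
    for g in covset.groups:
        if g.n <= 1:
            continue
        sigma = implied_sigma(theta, covset.q, group=g.name).sigma
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return _PENALTY
        _, logdet_s = np.linalg.slogdet(g.s)
        tr = float(np.trace(np.linalg.solve(sigma, g.s)))
        total += (g.n - 1) * (logdet + tr - logdet_s - len(sigma))
    return total


def _analytic_candidate(covset: GroupCovarianceSet):
    """Exact optimum under the consistency assumption (F = 0), or None.

    (o, m) solve the cross-covariances, residual variances absorb the
    phenotype variances and c the residual Y1-Y2 covariance.
    """
    q = covset.q
    by_name = {}
    for g in covset.groups:
        by_name.setdefault(g.name, g)
    own = by_name.get("own") or by_name.get("both")
    off = by_name.get("offspring") or by_name.get("both")
    if own is None or off is None:
        return None
    b1 = own.s[0, 1] / q
    v1 = own.s[1, 1]
    b2 = off.s[0, 1] / q if off.name != "both" else off.s[0, 2] / q
    v2 = off.s[1, 1] if off.name != "both" else off.s[2, 2]
    o = (4.0 * b1 - 2.0 * b2) / 3.0
    m = (4.0 * b2 - 2.0 * b1) / 3.0
    s1 = v1 - q * (o * o + m * m + o * m)
    s2 = v2 - q * (o * o + m * m + o * m)
    if s1 <= 0 or s2 <= 0:
        return None
    c = 0.0
    both = by_name.get("both")
    if both is not None and both.n > 0:
        c = both.s[1, 2] - (0.5 * q * (o * o + m * m) + 1.25 * o * m * q)
    return np.array([o, m, s1, s2, c])


def _hessian_fd(fun, theta, free_idx):
    """Central-difference Hessian of ``fun`` over the free parameters."""
    h = 1e-3 * np.maximum(np.abs(theta), 0.1)
    p = len(free_idx)
    hess = np.empty((p, p))

    def _at(shifts):
        t = theta.copy()
        for k, d in shifts:
            t[free_idx[k]] += d
        return fun(t)

    f0 = _at([])
    for i in range(p):
        hi = h[free_idx[i]]
        hess[i, i] = (_at([(i, hi)]) + _at([(i, -hi)]) - 2 * f0) / hi**2
        for j in range(i + 1, p):
            hj = h[free_idx[j]]
            hess[i, j] = hess[j, i] = (
                _at([(i, hi), (j, hj)])
                - _at([(i, hi), (j, -hj)])
                - _at([(i, -hi), (j, hj)])
                + _at([(i, -hi), (j, -hj)])
            ) / (4 * hi * hj)
    return hess


def fit_ml(
    covset: GroupCovarianceSet,
    model: PathModelSpec | None = None,
    start: np.ndarray | None = None,
    variant_id: str = "",
) -> SemFit:
    """Fit the SEM to one variant's group covariances by ML.

    The residual covariance c is free only when the both-phenotypes group is
    non-empty (with no both-group data there is nothing to estimate it from,
    so it is fixed at 0).  SEs come from the observed information; a
    non-positive-definite Hessian flags the SEs as missing (NaN).
    """
    if model is None:
        model = birthweight_model()
    if model.labels != ("offspring", "maternal"):
        raise ConfigurationError("the summary-statistics SEM is defined for the two-trait model")
    if not any(g.n > 1 for g in covset.groups):
        raise InputError("at least one group must have n > 1")

    c_free = covset.n_both > 1  # a both-group of n <= 1 carries no covariance information
    free_idx = [0, 1, 2, 3, 4] if c_free else [0, 1, 2, 3]

    candidate = _analytic_candidate(covset)
    n_restarts = 0
    converged = False
    theta_hat = None
    if candidate is not None:
        if not c_free:
            candidate[4] = 0.0
        f_cand = discrepancy(candidate, covset)
        if f_cand < 1e-9:
            theta_hat, f_min, converged = candidate, f_cand, True

    if theta_hat is None:
        # quasi-Newton on (o, m, log s1, log s2[, c]) to keep variances positive
        if start is None:
            start = candidate if candidate is not None else np.array([0.0, 0.0, 1.0, 1.0, 0.0])
        start = np.asarray(start, dtype=float)

        def pack(theta):
            x = [theta[0], theta[1], np.log(theta[2]), np.log(theta[3])]
            if c_free:
                x.append(theta[4])
            return np.array(x)

        def unpack(x):
            theta = np.array(
                [x[0], x[1], np.exp(x[2]), np.exp(x[3]), x[4] if c_free else 0.0]
            )
            return theta

        rng = np.random.default_rng(0)
        best = None
        start_clipped = np.maximum(start, [-np.inf, -np.inf, 1e-6, 1e-6, -np.inf])
        x0 = pack(start_clipped)
        for n_restarts in range(_MAX_RESTARTS + 1):
            res = optimize.minimize(
                lambda x: discrepancy(unpack(x), covset),
                x0,
                method="L-BFGS-B",
                options={"ftol": _F_TOL, "gtol": 1e-10, "maxiter": 500},
            )
            if best is None or res.fun < best.fun:
                best = res
            if res.success and res.fun < _PENALTY:
                converged = True
                break
            x0 = pack(start_clipped) + rng.normal(scale=0.1, size=len(x0))
        theta_hat = unpack(best.x)
        f_min = float(best.fun)

    nan = np.full(5, np.nan)
    if not converged:
        return SemFit(
            variant_id, ("offspring", "maternal"), nan, nan, np.full((5, 5), np.nan),
            f_min, False, c_free, np.array([np.nan, np.nan]), n_restarts,
        )

    hess = _hessian_fd(lambda t: 0.5 * discrepancy(t, covset), theta_hat, free_idx)
    se = np.full(5, np.nan)
    cov_theta = np.full((5, 5), np.nan)
    eig = np.linalg.eigvalsh(hess)
    if np.all(eig > 0):
        cov_free = np.linalg.inv(hess)
        cov_theta = np.zeros((5, 5))
        cov_theta[np.ix_(free_idx, free_idx)] = cov_free
        if not c_free:
            cov_theta[4, :] = cov_theta[:, 4] = np.nan
        se = np.sqrt(np.abs(np.diag(cov_theta)))
        if not c_free:
            se[4] = np.nan
    pvals = wald_p(theta_hat[:2], se[:2]) if np.all(np.isfinite(se[:2])) else np.array([np.nan, np.nan])
    return SemFit(
        variant_id, ("offspring", "maternal"), theta_hat, se, cov_theta,
        float(f_min), True, c_free, pvals, n_restarts,
    )


# ---------------------------------------------------------------------------
# vectorised table driver
# ---------------------------------------------------------------------------

def _batch_discrepancy(theta, data):
    """F(theta) for a batch of variants; theta is (B, 5), data a dict of arrays.

    Independent implementation of the group algebra in closed form (2x2
    groups) plus batched linear algebra (3x3 both-group); cross-checked
    against the scalar ``discrepancy`` in the test suite.
    """
    o, m, s1, s2, c = (theta[:, k] for k in range(5))
    q, b1, b2 = data["q"], data["b1"], data["b2"]
    v1, v2, rp = data["v1"], data["v2"], data["rp"]
    n1, n2, nb = data["n_own_only"], data["n_off_only"], data["n_both"]

    a1 = (o + 0.5 * m) * q
    a2 = (m + 0.5 * o) * q
    gvar = q * (o * o + m * m + o * m)
    d1 = gvar + s1
    d2 = gvar + s2

    f = np.zeros(len(q))
    bad = (s1 <= 0) | (s2 <= 0)

    def _two_group(n, a, d, b, v):
        det_sigma = q * d - a * a
        det_s = q * v - (b * q) ** 2
        ok = det_sigma > 0
        tr = (q * d - 2.0 * b * q * a + v * q) / np.where(ok, det_sigma, 1.0)
        contrib = np.where(
            ok,
            np.log(np.where(ok, det_sigma, 1.0)) + tr - np.log(det_s) - 2.0,
            _PENALTY,
        )
        return np.where(n > 1, (n - 1) * contrib, 0.0), ~ok

    f1, bad1 = _two_group(n1, a1, d1, b1, v1)
    f2, bad2 = _two_group(n2, a2, d2, b2, v2)
    f += f1 + f2
    bad |= bad1 | bad2

    has_both = nb > 1
    if np.any(has_both):
        idx = np.where(has_both)[0]
        bsz = len(idx)
        c12_obs = rp[idx] * np.sqrt(v1[idx] * v2[idx])
        c12_imp = 0.5 * q[idx] * (o[idx] ** 2 + m[idx] ** 2) + 1.25 * o[idx] * m[idx] * q[idx] + c[idx]
        sigma = np.empty((bsz, 3, 3))
        sigma[:, 0, 0] = q[idx]
        sigma[:, 0, 1] = sigma[:, 1, 0] = a1[idx]
        sigma[:, 0, 2] = sigma[:, 2, 0] = a2[idx]
        sigma[:, 1, 1] = d1[idx]
        sigma[:, 2, 2] = d2[idx]
        sigma[:, 1, 2] = sigma[:, 2, 1] = c12_imp
        s_obs = np.empty((bsz, 3, 3))
        s_obs[:, 0, 0] = q[idx]
        s_obs[:, 0, 1] = s_obs[:, 1, 0] = b1[idx] * q[idx]
        s_obs[:, 0, 2] = s_obs[:, 2, 0] = b2[idx] * q[idx]
        s_obs[:, 1, 1] = v1[idx]
        s_obs[:, 2, 2] = v2[idx]
        s_obs[:, 1, 2] = s_obs[:, 2, 1] = c12_obs
        sign, logdet = np.linalg.slogdet(sigma)
        ok = sign > 0
        _, logdet_s = np.linalg.slogdet(s_obs)
        tr = np.full(bsz, np.nan)
        if np.any(ok):
            sol = np.linalg.solve(sigma[ok], s_obs[ok])
            tr[ok] = np.trace(sol, axis1=1, axis2=2)
        contrib = np.where(ok, logdet + tr - logdet_s - 3.0, _PENALTY)
        f[idx] += (nb[idx] - 1) * contrib
        badb = np.zeros(len(q), dtype=bool)
        badb[idx[~ok]] = True
        bad |= badb

    return np.where(bad, _PENALTY, f)


def _batch_hessian(theta, data, free_idx):
    """Batched central-difference Hessian of F/2 over the free parameters."""
    b = theta.shape[0]
    p = len(free_idx)
    h = 1e-3 * np.maximum(np.abs(theta), 0.1)

    def _f(shifts):
        t = theta.copy()
        for k, sgn in shifts:
            t[:, free_idx[k]] += sgn * h[:, free_idx[k]]
        return 0.5 * _batch_discrepancy(t, data)

    f0 = _f([])
    hess = np.empty((b, p, p))
    for i in range(p):
        hi = h[:, free_idx[i]]
        hess[:, i, i] = (_f([(i, 1)]) + _f([(i, -1)]) - 2 * f0) / hi**2
        for j in range(i + 1, p):
            hj = h[:, free_idx[j]]
            hess[:, i, j] = hess[:, j, i] = (
                _f([(i, 1), (j, 1)])
                - _f([(i, 1), (j, -1)])
                - _f([(i, -1), (j, 1)])
                + _f([(i, -1), (j, -1)])
            ) / (4 * hi * hj)
    return hess


def sem_adjust_table(
    pair: HarmonizedSet,
    r_pheno: float,
    n_overlap: float = 0.0,
    model: PathModelSpec | None = None,
) -> pd.DataFrame:
    """Fit the SEM to every harmonized variant (own GWAS first, offspring second).

    ``n_overlap`` is the (estimated) number of individuals in both GWAS; the
    per-variant group sizes are n_own - n_overlap, n_off - n_overlap and
    n_overlap.  Per-variant fits are independent, so the output is identical
    under any partitioning of the table.  Variants where the fast analytic
    path is infeasible fall back to the scalar optimiser.
    """
    if model is None:
        model = birthweight_model()
    if len(pair.tables) != 2:
        raise ConfigurationError("sem_adjust_table needs exactly two harmonized tables")
    own, off = pair.tables[0], pair.tables[1]
    rec1, rec2 = own.records, off.records

    eaf = rec1["eaf"].to_numpy(float)
    q = 2.0 * eaf * (1.0 - eaf)
    b1 = rec1["beta"].to_numpy(float)
    b2 = rec2["beta"].to_numpy(float)
    n1 = rec1["n"].to_numpy(float)
    n2 = rec2["n"].to_numpy(float)
    nb = np.minimum(float(n_overlap), np.minimum(n1, n2))
    nvar = len(rec1)
    data = {
        "q": q,
        "b1": b1,
        "b2": b2,
        "v1": np.full(nvar, float(own.phenotype_variance)),
        "v2": np.full(nvar, float(off.phenotype_variance)),
        "rp": np.full(nvar, float(r_pheno)),
        "n_own_only": n1 - nb,
        "n_off_only": n2 - nb,
        "n_both": nb,
    }

    # analytic optimum (exact under the consistency assumption)
    o = (4.0 * b1 - 2.0 * b2) / 3.0
    m = (4.0 * b2 - 2.0 * b1) / 3.0
    gvar = q * (o * o + m * m + o * m)
    s1 = data["v1"] - gvar
    s2 = data["v2"] - gvar
    c = np.where(
        nb > 1,
        r_pheno * np.sqrt(data["v1"] * data["v2"])
        - (0.5 * q * (o * o + m * m) + 1.25 * o * m * q),
        0.0,
    )
    theta = np.column_stack([o, m, s1, s2, c])
    f_min = _batch_discrepancy(theta, data)
    analytic_ok = (s1 > 0) & (s2 > 0) & (f_min < 1e-9) & np.isfinite(b1) & np.isfinite(b2)

    se = np.full((nvar, 5), np.nan)
    cov_om = np.full(nvar, np.nan)
    converged = analytic_ok.copy()

    for c_free, sel in ((True, analytic_ok & (nb > 1)), (False, analytic_ok & (nb <= 1))):
        if not np.any(sel):
            continue
        free_idx = [0, 1, 2, 3, 4] if c_free else [0, 1, 2, 3]
        sub = {k: v[sel] for k, v in data.items()}
        hess = _batch_hessian(theta[sel], sub, free_idx)
        eig = np.linalg.eigvalsh(hess)
        pd_ok = np.all(eig > 0, axis=1)
        cov = np.full_like(hess, np.nan)
        if np.any(pd_ok):
            cov[pd_ok] = np.linalg.inv(hess[pd_ok])
        block = np.full((sel.sum(), 5), np.nan)
        block[:, free_idx] = np.sqrt(np.abs(np.diagonal(cov, axis1=1, axis2=2)))
        se[sel] = block
        cov_om[sel] = cov[:, 0, 1]

    # rare fall-back: variants the analytic path cannot handle
    for i in np.where(~analytic_ok)[0]:
        if not (np.isfinite(b1[i]) and np.isfinite(b2[i]) and 0 < eaf[i] < 1):
            converged[i] = False
            continue
        covset = build_group_covariances(
            b1[i], b2[i], eaf[i], r_pheno,
            data["n_own_only"][i], data["n_off_only"][i], nb[i],
            var_y1=own.phenotype_variance, var_y2=off.phenotype_variance,
        )
        fit = fit_ml(covset, model)
        theta[i] = fit.theta
        se[i] = fit.se
        cov_om[i] = fit.cov_theta[0, 1]
        f_min[i] = fit.f_min
        converged[i] = fit.converged

    out = pd.DataFrame(
        {
            "variant_id": rec1["variant_id"].to_numpy(),
            "chrom": rec1["chrom"].to_numpy(),
            "pos": rec1["pos"].to_numpy(),
            "effect_allele": rec1["effect_allele"].to_numpy(),
            "other_allele": rec1["other_allele"].to_numpy(),
            "eaf": eaf,
        }
    )
    for k, label in enumerate(("offspring", "maternal")):
        out[f"beta_{label}"] = theta[:, k]
        out[f"se_{label}"] = se[:, k]
        out[f"p_{label}"] = wald_p(theta[:, k], se[:, k])
        out[f"log10p_{label}"] = wald_log10p(theta[:, k], se[:, k])
    out["cov_offspring_maternal"] = cov_om
    out["sigma1_sq"] = theta[:, 2]
    out["sigma2_sq"] = theta[:, 3]
    out["c"] = np.where(nb > 1, theta[:, 4], 0.0)
    out["f_min"] = f_min
    out["converged"] = converged
    out["n_own"] = n1
    out["n_offspring"] = n2
    out["n_both"] = nb
    return out
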