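"""Synthetic family data, GWAS summary statistics and LDSC z-score panels.

The generator mirrors the estimators' data-generating assumptions so every
method in the package can be tested against known truth:

* three-generation families (mother, father, their offspring -- the "self"
  individual whose GWAS genotype is used -- plus a mate and a grandchild)
  with genotypes drawn under Hardy-Weinberg equilibrium and transmitted by
  fair Mendelian draws, giving parent-offspring genotype correlation 0.5 and
  grandmother-grandchild correlation 0.25 at scale;
* phenotypes built from per-variant conditional effects: own outcome
  Y1 = sum_j o_j G_self,j + m_j G_mother,j + e1 and offspring outcome
  Y2 = sum_j o_j G_child,j + m_j G_self,j + e2 with correlated Gaussian
  residuals (for the fertility model, one family-size outcome combining
  female, male and sibling-specific effects);
* per-SNP ordinary-least-squares GWAS on configurable, possibly overlapping
  subsamples, with the phenotype standardised within each subsample;
* z-score panels drawn directly from the bivariate LD score regression
  expectation, for testing the LDSC estimators with LD in play (family
  variants themselves are simulated in linkage equilibrium, since the
  per-variant estimators never use LD).

By default residual scales are completed so each phenotype has unit total
variance (the phenotypes are z-scored, as in the birth weight GWAS this
emulates) and the residual correlation is solved so the total phenotypic
correlation between the paired phenotypes equals 0.24.  One master seed is
expanded into independent child streams (founder genotypes, transmission,
noise, masks, z-panels) so each component is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .path_models import PathModelSpec, birthweight_model
from .sumstats_io import InputError, LDScorePanel, SumstatsTable

__all__ = [
    "SimConfig",
    "FamilyDataset",
    "simulate_families",
    "run_gwas",
    "make_overlap_design",
    "simulate_ldsc_zscores",
    "make_ld_panel",
    "implied_phenotypic_correlation",
]

#: total phenotypic correlation between own and offspring birth weight used
#: throughout: the value estimated in the cohort the generator emulates.
DEFAULT_PHENO_CORR = 0.24


@dataclass
class SimConfig:
    """Conditions for one synthetic study.

    ``true_effects`` holds one conditional-effect vector per variant, ordered
    as ``model.labels`` ((o, m) for the birth weight model); default zeros.
    ``allele_freqs`` default to Uniform(0.05, 0.95) draws.  ``residual_sd``
    of None completes each phenotype to unit total variance; a
    ``residual_corr`` of None is solved so the total correlation between the
    paired phenotypes equals ``target_pheno_corr`` (birth weight model only;
    the fertility model has a single outcome).
    """

    n_families: int
    n_variants: int
    seed: int = 0
    allele_freqs: np.ndarray | None = None
    true_effects: np.ndarray | None = None
    residual_sd: tuple[float, ...] | None = None
    residual_corr: float | None = None
    target_pheno_corr: float = DEFAULT_PHENO_CORR
    overlap_fraction: float = 0.0
    model: PathModelSpec = field(default_factory=birthweight_model)

    def __post_init__(self) -> None:
        if self.n_families <= 0 or self.n_variants <= 0:
            raise InputError("n_families and n_variants must be positive")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise InputError("overlap_fraction must lie in [0, 1]")
        if self.residual_corr is not None and not -1 < self.residual_corr < 1:
            raise InputError("residual_corr must lie in (-1, 1)")
        if self.allele_freqs is not None:
            f = np.asarray(self.allele_freqs, dtype=float)
            if f.shape != (self.n_variants,) or np.any((f <= 0) | (f >= 1)):
                raise InputError("allele_freqs must be n_variants values in (0, 1)")
        if self.true_effects is not None:
            eff = np.atleast_2d(np.asarray(self.true_effects, dtype=float))
            if eff.shape != (self.n_variants, self.model.k):
                raise InputError(
                    "true_effects must have shape (n_variants, K) matching the model"
                )


@dataclass
class FamilyDataset:
    """Simulated genotypes and phenotypes for n_families independent families.

    ``genotypes`` maps member names (mother, father, self, mate, child) to
    (n_families, n_variants) dosage arrays; ``phenotypes`` maps outcome names
    ("own"/"offspring" for the birth weight model, "fertility" otherwise) to
    length-n_families arrays.
    """

    config: SimConfig
    allele_freqs: np.ndarray
    true_effects: np.ndarray
    genotypes: dict[str, np.ndarray]
    phenotypes: dict[str, np.ndarray]
    residual_sd: tuple[float, ...]
    residual_corr: float
    pheno_corr: float | None  # implied total correlation (birth weight model)


def _child_seeds(seed: int, n: int):
    return np.random.SeedSequence(seed).spawn(n)


def _gamete(g: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One transmitted allele per locus: alt with probability dosage/2."""
    return (rng.random(g.shape) < g / 2.0).astype(np.int8)


def _genetic_moments(freqs, effects, model_labels):
    """Analytic variance/covariance contributions of the simulated variants."""
    q = 2.0 * freqs * (1.0 - freqs)
    if len(model_labels) == 2:  # birth weight (o, m)
        o, m = effects[:, 0], effects[:, 1]
        gvar = float(np.sum(q * (o * o + m * m + o * m)))
        gcov = float(np.sum(q * (0.5 * (o * o + m * m) + 1.25 * o * m)))
        return gvar, gcov
    f, m, s = effects[:, 0], effects[:, 1], effects[:, 2]
    gvar = float(np.sum(q * (f * f + m * m + s * s + f * s + m * s)))
    return gvar, None


def _resolve_residuals(config: SimConfig, freqs, effects):
    """Residual SDs/correlation honouring the unit-variance default."""
    labels = config.model.labels
    n_pheno = 2 if labels == ("offspring", "maternal") else 1
    gvar, gcov = _genetic_moments(freqs, effects, labels)
    if config.residual_sd is not None:
        sds = tuple(float(s) for s in np.atleast_1d(config.residual_sd))
        if len(sds) == 1:
            sds = sds * n_pheno
    else:
        if gvar >= 1.0:
            raise InputError(
                f"genetic variance {gvar:.3f} >= 1; cannot complete to unit "
                "phenotype variance (pass residual_sd explicitly)"
            )
        sds = (float(np.sqrt(1.0 - gvar)),) * n_pheno
    if n_pheno == 1:
        return sds, 0.0, None
    if config.residual_corr is not None:
        rho = float(config.residual_corr)
    else:
        rho = (config.target_pheno_corr * np.sqrt(gvar + sds[0] ** 2)
               * np.sqrt(gvar + sds[1] ** 2) - gcov) / (sds[0] * sds[1])
        if not -1 < rho < 1:
            raise InputError(
                f"target phenotypic correlation {config.target_pheno_corr} "
                f"requires residual correlation {rho:.3f} outside (-1, 1)"
            )
    total_corr = (gcov + rho * sds[0] * sds[1]) / (
        np.sqrt(gvar + sds[0] ** 2) * np.sqrt(gvar + sds[1] ** 2)
    )
    return sds, rho, float(total_corr)


def implied_phenotypic_correlation(data: FamilyDataset) -> float:
    """Total correlation between the paired phenotypes implied by the config."""
    if data.pheno_corr is None:
        raise InputError("phenotypic correlation is defined for paired phenotypes only")
    return data.pheno_corr


def simulate_families(config: SimConfig) -> FamilyDataset:
    """Draw genotypes under HWE with Mendelian transmission, then phenotypes."""
    seeds = _child_seeds(config.seed, 4)
    rng_freq = np.random.default_rng(seeds[0])
    rng_geno = np.random.default_rng(seeds[1])
    rng_noise = np.random.default_rng(seeds[2])

    nf, nv = config.n_families, config.n_variants
    freqs = (
        np.asarray(config.allele_freqs, dtype=float)
        if config.allele_freqs is not None
        else rng_freq.uniform(0.05, 0.95, size=nv)
    )
    effects = (
        np.atleast_2d(np.asarray(config.true_effects, dtype=float))
        if config.true_effects is not None
        else np.zeros((nv, config.model.k))
    )

    mother = rng_geno.binomial(2, freqs, size=(nf, nv)).astype(np.int8)
    father = rng_geno.binomial(2, freqs, size=(nf, nv)).astype(np.int8)
    mate = rng_geno.binomial(2, freqs, size=(nf, nv)).astype(np.int8)
    self_ = _gamete(mother, rng_geno) + _gamete(father, rng_geno)
    child = _gamete(self_, rng_geno) + _gamete(mate, rng_geno)
    genotypes = {
        "mother": mother,
        "father": father,
        "self": self_,
        "mate": mate,
        "child": child,
    }

    sds, rho, total_corr = _resolve_residuals(config, freqs, effects)
    labels = config.model.labels
    if labels == ("offspring", "maternal"):
        o, m = effects[:, 0], effects[:, 1]
        e1 = rng_noise.standard_normal(nf)
        e2 = rho * e1 + np.sqrt(1.0 - rho * rho) * rng_noise.standard_normal(nf)
        y1 = self_ @ o + mother @ m + sds[0] * e1
        y2 = child @ o + self_ @ m + sds[1] * e2
        phenotypes = {"own": y1, "offspring": y2}
    else:
        # fertility-style single family-size outcome; "self" is the offspring
        # reporting sibling count, mother/father carry the parental effects
        f, mm, s = effects[:, 0], effects[:, 1], effects[:, 2]
        e = rng_noise.standard_normal(nf)
        pheno = mother @ f + father @ mm + self_ @ s + sds[0] * e
        phenotypes = {"fertility": pheno}

    return FamilyDataset(
        config=config,
        allele_freqs=freqs,
        true_effects=effects,
        genotypes=genotypes,
        phenotypes=phenotypes,
        residual_sd=sds,
        residual_corr=rho,
        pheno_corr=total_corr,
    )


def run_gwas(
    data: FamilyDataset,
    genotype: str = "self",
    phenotype: str = "own",
    mask: np.ndarray | None = None,
    trait_label: str | None = None,
) -> SumstatsTable:
    """Per-variant OLS GWAS of one phenotype on one family member's genotype.

    The phenotype is standardised within the (possibly masked) subsample.
    Monomorphic variants in the subsample are emitted with NaN beta/se and
    ``monomorphic`` set, rather than dropped, so variant lists stay aligned.
    """
    g_all = data.genotypes[genotype]
    y_all = data.phenotypes[phenotype]
    if mask is None:
        mask = np.ones(len(y_all), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InputError("run_gwas mask selects no samples")
    g = g_all[mask].astype(np.float64)
    y = y_all[mask]
    n = len(y)
    y = (y - y.mean()) / y.std()

    g_mean = g.mean(axis=0)
    gc = g - g_mean
    sxx = np.einsum("ij,ij->j", gc, gc)
    sxy = gc.T @ y
    syy = float(y @ y)  # == n after standardisation
    mono = sxx <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(mono, np.nan, sxy / np.where(mono, 1.0, sxx))
        rss = syy - beta * beta * sxx
        se = np.sqrt(rss / ((n - 2) * sxx))
    beta[mono] = np.nan
    se[mono] = np.nan

    nv = g.shape[1]
    records = pd.DataFrame(
        {
            "variant_id": [f"snp{j + 1:06d}" for j in range(nv)],
            "chrom": "1",
            "pos": np.arange(1, nv + 1, dtype=np.int64) * 100_000,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": g_mean / 2.0,
            "beta": beta,
            "se": se,
            "n": n,
            "monomorphic": mono,
        }
    )
    label = trait_label or f"{phenotype}_on_{genotype}"
    return SumstatsTable(label, records, phenotype_variance=1.0)


def make_overlap_design(n_families: int, overlap_fraction: float, seed: int = 0):
    """Two subsample masks whose intersection is round(fraction * n_families).

    The shared block plays the "both phenotypes reported" role; the remaining
    families are split evenly between the two single-phenotype GWAS, so the
    union covers all families.  fraction 0 gives disjoint halves, fraction 1
    identical masks.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise InputError("overlap_fraction must lie in [0, 1]")
    rng = np.random.default_rng(_child_seeds(seed, 4)[3])
    n_both = int(round(overlap_fraction * n_families))
    perm = rng.permutation(n_families)
    rest = perm[n_both:]
    half = len(rest) // 2
    mask_a = np.zeros(n_families, dtype=bool)
    mask_b = np.zeros(n_families, dtype=bool)
    mask_a[perm[:n_both]] = True
    mask_b[perm[:n_both]] = True
    mask_a[rest[:half]] = True
    mask_b[rest[half:]] = True
    return mask_a, mask_b


def make_ld_panel(n_variants: int, seed: int = 0, mean_excess: float = 30.0, m: int | None = None) -> LDScorePanel:
    """Synthetic LD-score panel: scores 1 + Gamma(2, mean_excess / 2) draws."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    scores = 1.0 + rng.gamma(shape=2.0, scale=mean_excess / 2.0, size=n_variants)
    records = pd.DataFrame(
        {
            "variant_id": [f"snp{j + 1:06d}" for j in range(n_variants)],
            "ld_score": scores,
        }
    )
    return LDScorePanel(records, m if m is not None else n_variants)


def simulate_ldsc_zscores(
    ld: LDScorePanel,
    h2_1: float,
    h2_2: float,
    rg: float,
    n1: int,
    n2: int,
    n_overlap: float = 0.0,
    r_pheno: float = DEFAULT_PHENO_CORR,
    seed: int = 0,
):
    """Paired z-scores following the bivariate LDSC expectation.

    Per variant j, (z1, z2) is bivariate normal with

        Var(z_i)      = 1 + n_i h2_i l_j / M
        Cov(z1, z2)   = sqrt(n1 n2) rg sqrt(h2_1 h2_2) l_j / M
                        + n_overlap r_pheno / sqrt(n1 n2)

    Returns two aligned numpy arrays in the panel's variant order.
    """
    for h2 in (h2_1, h2_2):
        if not 0.0 <= h2 <= 1.0:
            raise InputError("h2 must lie in [0, 1]")
    if abs(rg) > 1:
        raise InputError("|rg| must be <= 1")
    if not 0 <= n_overlap <= min(n1, n2):
        raise InputError("n_overlap must lie in [0, min(n1, n2)]")
    scores = ld.records["ld_score"].to_numpy(float)
    lm = scores / ld.m
    v1 = 1.0 + n1 * h2_1 * lm
    v2 = 1.0 + n2 * h2_2 * lm
    cov = np.sqrt(n1 * n2 * h2_1 * h2_2) * rg * lm + n_overlap * r_pheno / np.sqrt(
        float(n1) * float(n2)
    )
    resid = v2 - cov * cov / v1
    if np.any(resid <= 0):
        raise InputError("per-variant z-score covariance matrix is not positive definite")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    u1 = rng.standard_normal(len(scores))
    u2 = rng.standard_normal(len(scores))
    z1 = np.sqrt(v1) * u1
    z2 = (cov / np.sqrt(v1)) * u1 + np.sqrt(resid) * u2
    return z1, z2
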