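import numpy as np
import pandas as pd
import pytest

from famcond.sumstats_io import HarmonizedSet, SumstatsTable


def make_table(
    label="trait",
    variant_ids=("rs1", "rs2", "rs3"),
    chrom="1",
    pos=None,
    ea="A",
    oa="G",
    eaf=0.3,
    beta=0.1,
    se=0.02,
    n=10000,
):
    """Small in-memory summary table with scalar or per-variant fields."""
    nv = len(variant_ids)

    def _vec(x):
        return np.repeat(x, nv) if np.ndim(x) == 0 else np.asarray(x)

    records = pd.DataFrame(
        {
            "variant_id": list(variant_ids),
            "chrom": _vec(chrom).astype(str),
            "pos": _vec(pos if pos is not None else np.arange(1, nv + 1) * 1000),
            "effect_allele": _vec(ea),
            "other_allele": _vec(oa),
            "eaf": _vec(eaf).astype(float),
            "beta": _vec(beta).astype(float),
            "se": _vec(se).astype(float),
            "n": _vec(n),
        }
    )
    return SumstatsTable(label, records)


def make_harmonized(tables):
    """Wrap pre-aligned tables without re-running harmonization."""
    return HarmonizedSet(list(tables), pd.DataFrame(columns=["variant_id", "reason"]))


def sample_null_pair(n_var, n1, n2, n_overlap, r_pheno, seed):
    """Draw null unadjusted GWAS betas from their exact sampling distribution.

    Standardised phenotypes and HWE genotypes give se_i = 1/sqrt(n_i q) and
    error correlation n_overlap * r_pheno / sqrt(n1 n2) between the two GWAS
    at the same variant.
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, n_var)
    q = 2 * p * (1 - p)
    se1 = 1.0 / np.sqrt(n1 * q)
    se2 = 1.0 / np.sqrt(n2 * q)
    c = n_overlap * r_pheno / np.sqrt(n1 * n2)
    u1 = rng.standard_normal(n_var)
    u2 = rng.standard_normal(n_var)
    b1 = se1 * u1
    b2 = se2 * (c * u1 + np.sqrt(1 - c * c) * u2)
    ids = [f"snp{j + 1:06d}" for j in range(n_var)]
    t1 = make_table("own", ids, eaf=p, beta=b1, se=se1, n=n1)
    t2 = make_table("offspring", ids, eaf=p, beta=b2, se=se2, n=n2)
    return make_harmonized([t1, t2]), c


@pytest.fixture(scope="session")
def birthweight_sim_pair():
    """Family simulation + two GWAS with no sample overlap (shared fixture)."""
    from famcond import simulate as sim

    n_fam, n_var = 20000, 200
    cfg = sim.SimConfig(
        n_families=n_fam,
        n_variants=n_var,
        seed=7,
        true_effects=np.tile([0.06, -0.04], (n_var, 1)),
        overlap_fraction=0.0,
    )
    data = sim.simulate_families(cfg)
    mask_own, mask_off = sim.make_overlap_design(n_fam, 0.0, cfg.seed)
    own = sim.run_gwas(data, "self", "own", mask_own, "own")
    off = sim.run_gwas(data, "self", "offspring", mask_off, "offspring")
    return data, make_harmonized([own, off]), mask_own, mask_off
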