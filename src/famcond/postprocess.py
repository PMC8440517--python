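"""Between-method heterogeneity tests, locus counting and novelty flags.

A locus is a window of +/- ``window_bp`` (500 kb by default) around a
sentinel SNP, the most significant variant not already covered by a chosen
sentinel.  Novelty against a known-sentinel list uses the strict reading of
"greater than 500 kb from the known sentinel": a locus exactly at the window
edge still counts as known.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats_io import InputError

__all__ = [
    "LocusSet",
    "heterogeneity_test",
    "heterogeneity_table",
    "count_loci",
    "classify_novel",
]

GENOME_WIDE_ALPHA = 5e-8
DEFAULT_WINDOW_BP = 500_000


@dataclass
class LocusSet:
    """Sentinel SNPs of independent loci at a significance threshold."""

    sentinels: pd.DataFrame  # variant_id, chrom, pos, p
    window_bp: int
    alpha: float

    @property
    def n_loci(self) -> int:
        return len(self.sentinels)


def heterogeneity_test(beta1, se1, beta2, se2):
    """Cochran-style heterogeneity between two estimates of the same effect.

    Q = (beta1 - beta2)^2 / (se1^2 + se2^2), p from chi-square with 1 df.
    Accepts scalars or aligned arrays.  The test treats the two estimators
    as independent; applied to two methods run on the same data it ignores
    their correlation.
    """
    se1 = np.asarray(se1, dtype=float)
    se2 = np.asarray(se2, dtype=float)
    if np.any(se1 <= 0) or np.any(se2 <= 0):
        raise InputError("standard errors must be positive")
    q = (np.asarray(beta1, float) - np.asarray(beta2, float)) ** 2 / (se1**2 + se2**2)
    p = stats.chi2.sf(q, df=1)
    if np.ndim(q) == 0:
        return float(q), float(p)
    return q, p


def heterogeneity_table(a: pd.DataFrame, b: pd.DataFrame, labels) -> pd.DataFrame:
    """Per-variant heterogeneity between two result tables, per effect label.

    Tables are joined on variant_id; a ``bonferroni_alpha`` attribute records
    0.05 / n_variants for the significance calls reported alongside.
    """
    merged = a.merge(b, on="variant_id", suffixes=("_a", "_b"))
    if merged.empty:
        raise InputError("no shared variants between result tables")
    out = pd.DataFrame({"variant_id": merged["variant_id"]})
    for label in labels:
        q, p = heterogeneity_test(
            merged[f"beta_{label}_a"],
            merged[f"se_{label}_a"],
            merged[f"beta_{label}_b"],
            merged[f"se_{label}_b"],
        )
        out[f"q_{label}"] = q
        out[f"p_{label}"] = p
    out.attrs["bonferroni_alpha"] = 0.05 / len(merged)
    return out


def count_loci(
    results: pd.DataFrame,
    alpha: float = GENOME_WIDE_ALPHA,
    window_bp: int = DEFAULT_WINDOW_BP,
    p_col: str = "p",
) -> LocusSet:
    """Greedy sentinel selection among variants with p < alpha.

    Repeatedly takes the smallest-p remaining variant not within
    ``window_bp`` of an already chosen sentinel on the same chromosome.
    Ties on p break deterministically by (chrom, pos, variant_id), so the
    result does not depend on input row order.
    """
    cols = {"variant_id", "chrom", "pos", p_col}
    if not cols.issubset(results.columns):
        raise InputError(f"results table needs columns {sorted(cols)}")
    sig = results.loc[results[p_col] < alpha, ["variant_id", "chrom", "pos", p_col]]
    sig = sig.rename(columns={p_col: "p"})
    sig = sig.sort_values(
        ["p", "chrom", "pos", "variant_id"], kind="mergesort"
    ).reset_index(drop=True)
    chosen: list[int] = []
    chosen_by_chrom: dict[str, list[int]] = {}
    for i in range(len(sig)):
        chrom = sig.at[i, "chrom"]
        pos = sig.at[i, "pos"]
        near = chosen_by_chrom.get(chrom, [])
        if any(abs(pos - p0) <= window_bp for p0 in near):
            continue
        chosen.append(i)
        chosen_by_chrom.setdefault(chrom, []).append(pos)
    return LocusSet(
        sentinels=sig.loc[chosen].reset_index(drop=True),
        window_bp=int(window_bp),
        alpha=float(alpha),
    )


def classify_novel(
    loci: LocusSet, known, window_bp: int | None = None
) -> pd.DataFrame:
    """Flag each locus as known or novel against a known-sentinel list.

    ``known`` is a DataFrame with (chrom, pos) columns or an iterable of
    (chrom, pos) pairs.  A locus is known iff it lies within ``window_bp``
    of a known sentinel on the same chromosome; strictly farther than the
    window is novel.  An empty known list marks every locus novel.
    """
    if window_bp is None:
        window_bp = loci.window_bp
    if isinstance(known, pd.DataFrame):
        pairs = list(zip(known["chrom"].astype(str), known["pos"].astype(int)))
    else:
        pairs = [(str(c), int(p)) for c, p in known]
    by_chrom: dict[str, list[int]] = {}
    for c, p in pairs:
        by_chrom.setdefault(c, []).append(p)
    out = loci.sentinels.copy()
    flags = []
    for chrom, pos in zip(out["chrom"].astype(str), out["pos"]):
        near = by_chrom.get(chrom, [])
        flags.append(any(abs(int(pos) - p0) <= window_bp for p0 in near))
    out["known"] = flags
    out["novel"] = ~out["known"]
    return out
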