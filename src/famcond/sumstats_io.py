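"""Reading, validation, harmonization and writing of GWAS summary statistics.

Summary-statistics tables are whitespace- or tab-delimited text files with a
header row.  Column names are configurable through ``column_map``; internally
every table is normalised to the standard columns

    variant_id, chrom, pos, effect_allele, other_allele, eaf, beta, se, n[, info]

with ``beta`` the per-allele effect on the (standardised) phenotype.  Rows
failing basic sanity checks (non-positive standard error, allele frequency
outside (0, 1), identical alleles, ...) are dropped and logged with a reason
code rather than aborting the whole read.

Harmonization aligns two or more tables to a shared variant list and a single
effect-allele orientation, flipping beta signs and allele frequencies where
the allele labels are swapped, and applying the minor-allele-frequency and
strand-ambiguity exclusions used for model fitting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("famcond")

__all__ = [
    "ConfigurationError",
    "InputError",
    "SumstatsTable",
    "HarmonizedSet",
    "LDScorePanel",
    "read_sumstats",
    "write_sumstats",
    "harmonize",
    "read_ldscores",
    "STANDARD_COLUMNS",
]


class ConfigurationError(ValueError):
    """A caller-supplied option or mapping is inconsistent with the inputs."""


class InputError(ValueError):
    """The input data themselves are unusable (empty, unparseable, ...)."""


#: required standard columns, in canonical output order
STANDARD_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "n",
)

_OPTIONAL_COLUMNS = ("info",)

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: maximum tolerated effect-allele-frequency disagreement between tables for
#: the same (harmonized) variant; larger gaps indicate strand or ID errors.
EAF_MISMATCH_MAX = 0.2


@dataclass
class SumstatsTable:
    """Per-variant GWAS summary records for one trait.

    ``records`` is a DataFrame using the standard column names; variant IDs
    are unique within a table.  ``phenotype_variance`` is 1 for traits that
    were z-scored before the GWAS (the usual case here).
    """

    trait_label: str
    records: pd.DataFrame
    phenotype_variance: float = 1.0
    dropped_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variant_id", "reason"])
    )

    def __post_init__(self) -> None:
        if self.phenotype_variance <= 0:
            raise ConfigurationError("phenotype_variance must be positive")
        ids = self.records["variant_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise InputError(f"duplicate variant_id in table {self.trait_label!r}: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def zscores(self) -> np.ndarray:
        return (self.records["beta"] / self.records["se"]).to_numpy(float)


@dataclass
class HarmonizedSet:
    """K summary tables aligned on an identical variant list and orientation."""

    tables: list[SumstatsTable]
    dropped_log: pd.DataFrame

    def __post_init__(self) -> None:
        lengths = {len(t) for t in self.tables}
        if len(lengths) > 1:
            raise InputError("harmonized tables must all have the same length")

    def __len__(self) -> int:
        return len(self.tables[0])

    @property
    def variant_ids(self) -> pd.Series:
        return self.tables[0].records["variant_id"]


@dataclass
class LDScorePanel:
    """Per-variant LD scores with the genome-wide variant count M.

    A variant is always in LD with itself, so scores below 1 are floored at 1
    on construction.
    """

    records: pd.DataFrame  # variant_id, ld_score[, weight]
    m: int

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ConfigurationError("n_variants_genomewide M must be positive")
        low = self.records["ld_score"] < 1.0
        if low.any():
            logger.warning("flooring %d LD scores below 1 at 1", int(low.sum()))
            self.records = self.records.copy()
            self.records.loc[low, "ld_score"] = 1.0
        if "weight" in self.records.columns and (self.records["weight"] <= 0).any():
            raise InputError("LD-score regression weights must be positive")

    def __len__(self) -> int:
        return len(self.records)


def _resolve_columns(columns, column_map):
    """Map standard names to file column names, erroring on missing ones."""
    column_map = dict(column_map or {})
    resolved = {}
    for std in STANDARD_COLUMNS + _OPTIONAL_COLUMNS:
        name = column_map.get(std, std)
        if name in columns:
            resolved[std] = name
        elif std in STANDARD_COLUMNS:
            raise ConfigurationError(
                f"required column {std!r} (file column {name!r}) not found; "
                f"available: {list(columns)}"
            )
    return resolved


def read_sumstats(
    path,
    column_map: dict | None = None,
    phenotype_variance: float = 1.0,
    trait_label: str | None = None,
) -> SumstatsTable:
    """Read one GWAS summary-statistics table from delimited text.

    Parameters
    ----------
    path
        Tab- or whitespace-delimited text file with a header; ``.gz`` files
        are decompressed transparently.
    column_map
        Mapping from standard column names to the names used in the file,
        e.g. ``{"variant_id": "SNP", "eaf": "FREQ1"}``.  Unmapped standard
        names are looked up verbatim.
    phenotype_variance
        Variance of the phenotype the betas refer to (1 if standardised).

    Rows that fail type or invariant checks are dropped and recorded in the
    returned table's ``dropped_log`` with a reason code.
    """
    raw = pd.read_csv(path, sep=r"\s+", compression="infer", dtype=str)
    if raw.empty:
        raise InputError(f"no data rows in {path}")
    resolved = _resolve_columns(raw.columns, column_map)
    df = pd.DataFrame({std: raw[name] for std, name in resolved.items()})

    drops: list[tuple[str, str]] = []

    def _drop(mask: pd.Series, reason: str) -> None:
        nonlocal df
        bad = df.loc[mask, "variant_id"]
        drops.extend((str(v), reason) for v in bad)
        df = df.loc[~mask]

    df["variant_id"] = df["variant_id"].astype(str)
    _drop(df["variant_id"].isin(("", "nan", "NA", ".")), "missing variant_id")

    for col, reason in (
        ("pos", "unparseable pos"),
        ("eaf", "unparseable eaf"),
        ("beta", "unparseable beta"),
        ("se", "unparseable se"),
        ("n", "unparseable n"),
    ):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        _drop(~np.isfinite(df[col].to_numpy(float)), reason)
    if "info" in df.columns:
        df["info"] = pd.to_numeric(df["info"], errors="coerce")

    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    _drop(
        ~(
            df["effect_allele"].isin(_VALID_ALLELES)
            & df["other_allele"].isin(_VALID_ALLELES)
        ),
        "invalid allele",
    )
    _drop(df["effect_allele"] == df["other_allele"], "identical alleles")
    _drop(~((df["eaf"] > 0) & (df["eaf"] < 1)), "eaf outside (0,1)")
    _drop(df["se"] <= 0, "nonpositive se")
    _drop(df["n"] <= 0, "nonpositive n")
    _drop(df["pos"] <= 0, "nonpositive pos")
    if "info" in df.columns:
        bad_info = np.isfinite(df["info"].to_numpy(float)) & (
            (df["info"] < 0) | (df["info"] > 1)
        )
        _drop(pd.Series(bad_info, index=df.index), "info outside [0,1]")

    if df.empty:
        raise InputError(f"zero parseable rows in {path}")

    df = df.astype({"pos": np.int64})
    df["chrom"] = df["chrom"].astype(str)
    df = df.reset_index(drop=True)
    label = trait_label if trait_label is not None else str(path)
    dropped = pd.DataFrame(drops, columns=["variant_id", "reason"])
    if len(dropped):
        logger.info("read_sumstats(%s): dropped %d rows", path, len(dropped))
    return SumstatsTable(label, df, phenotype_variance, dropped)


def write_sumstats(table: SumstatsTable, path) -> None:
    """Write a table with the fixed output header.

    Columns: variant_id, chrom, pos, effect_allele, other_allele, eaf,
    beta_<label>, se_<label>, p_<label>, n.  The p-value is the two-sided
    normal Wald p recomputed from beta and se.
    """
    df = table.records
    label = table.trait_label
    z = df["beta"].to_numpy(float) / df["se"].to_numpy(float)
    out = pd.DataFrame(
        {
            "variant_id": df["variant_id"],
            "chrom": df["chrom"],
            "pos": df["pos"],
            "effect_allele": df["effect_allele"],
            "other_allele": df["other_allele"],
            "eaf": df["eaf"],
            f"beta_{label}": df["beta"],
            f"se_{label}": df["se"],
            f"p_{label}": 2.0 * stats.norm.sf(np.abs(z)),
            "n": df["n"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def _is_strand_ambiguous(ea: str, oa: str) -> bool:
    return _COMPLEMENT[ea] == oa


def harmonize(
    tables: list[SumstatsTable],
    maf_min: float = 0.0,
    drop_strand_ambiguous: bool = False,
) -> HarmonizedSet:
    """Align K >= 2 summary tables to one variant list and allele orientation.

    The shared variants are oriented canonically (effect allele first in
    alphabetical order), so the result does not depend on which table the
    caller lists first.  For each non-canonical table the beta sign is
    flipped and the frequency replaced by ``1 - eaf``.  Variants are dropped,
    with a reason code in ``dropped_log``, when they are

    - absent from at least one table (``not_shared``),
    - A/T or C/G and ``drop_strand_ambiguous`` is set (``strand_ambiguous``),
    - carrying allele labels that cannot be reconciled by swapping (and, for
      unambiguous variants when ``drop_strand_ambiguous`` is off, by exact
      strand complementing) (``allele_mismatch``),
    - disagreeing in frequency by more than 0.2 after orientation
      (``eaf_mismatch``), or
    - rarer than ``maf_min`` in any table (``maf``).

    ``maf_min`` defaults to 0; the summary-statistics SEM is fit with 0.005
    because it optimises poorly at low minor allele frequencies.
    """
    if len(tables) < 2:
        raise ConfigurationError("harmonize needs at least two tables")

    indexed = [t.records.set_index("variant_id", drop=False) for t in tables]
    shared = indexed[0].index
    for idx in indexed[1:]:
        shared = shared.intersection(idx.index)
    if len(shared) == 0:
        raise InputError("no variants shared across all tables")
    # keep first-table row order for determinism
    shared = indexed[0].index[indexed[0].index.isin(shared)]

    drops: dict[str, str] = {}
    union: set[str] = set()
    for idx in indexed:
        union.update(idx.index)
    for vid in union:
        if vid not in shared:
            drops[vid] = "not_shared"

    frames = [idx.loc[shared].copy() for idx in indexed]
    ref = frames[0]

    # warn (once per table) when chrom/pos disagree for shared IDs
    for k, frame in enumerate(frames[1:], start=1):
        mism = (frame["chrom"].to_numpy() != ref["chrom"].to_numpy()) | (
            frame["pos"].to_numpy() != ref["pos"].to_numpy()
        )
        if mism.any():
            logger.warning(
                "harmonize: %d shared variants have chrom/pos disagreeing "
                "between table 0 and table %d (positions are the caller's "
                "responsibility)",
                int(mism.sum()),
                k,
            )

    ambiguous = {
        vid
        for vid, ea, oa in zip(ref.index, ref["effect_allele"], ref["other_allele"])
        if _is_strand_ambiguous(ea, oa)
    }
    if drop_strand_ambiguous:
        for vid in ambiguous:
            drops[vid] = "strand_ambiguous"

    # canonical orientation: effect allele alphabetically first
    for frame in frames:
        flip = frame["effect_allele"] > frame["other_allele"]
        if flip.any():
            ea = frame.loc[flip, "effect_allele"].copy()
            frame.loc[flip, "effect_allele"] = frame.loc[flip, "other_allele"]
            frame.loc[flip, "other_allele"] = ea
            frame.loc[flip, "beta"] = -frame.loc[flip, "beta"]
            frame.loc[flip, "eaf"] = 1.0 - frame.loc[flip, "eaf"]

    allow_strand_flip = not drop_strand_ambiguous
    for frame in frames[1:]:
        same = (frame["effect_allele"] == ref["effect_allele"]) & (
            frame["other_allele"] == ref["other_allele"]
        )
        for vid in frame.index[~same]:
            if vid in drops:
                continue
            ea, oa = frame.at[vid, "effect_allele"], frame.at[vid, "other_allele"]
            rea, roa = ref.at[vid, "effect_allele"], ref.at[vid, "other_allele"]
            cea, coa = _COMPLEMENT[ea], _COMPLEMENT[oa]
            if allow_strand_flip and vid not in ambiguous and {cea, coa} == {rea, roa}:
                # exact strand complement; re-orient canonically afterwards
                if (cea, coa) == (rea, roa):
                    frame.loc[vid, ["effect_allele", "other_allele"]] = [cea, coa]
                else:
                    frame.loc[vid, ["effect_allele", "other_allele"]] = [coa, cea]
                    frame.at[vid, "beta"] = -frame.at[vid, "beta"]
                    frame.at[vid, "eaf"] = 1.0 - frame.at[vid, "eaf"]
            else:
                drops[vid] = "allele_mismatch"

    # frequency-consistency check after orientation
    for frame in frames[1:]:
        gap = (frame["eaf"].to_numpy(float) - ref["eaf"].to_numpy(float))
        for vid in frame.index[np.abs(gap) > EAF_MISMATCH_MAX]:
            drops.setdefault(vid, "eaf_mismatch")

    if maf_min > 0:
        for frame in frames:
            eaf = frame["eaf"].to_numpy(float)
            maf = np.minimum(eaf, 1.0 - eaf)
            for vid in frame.index[maf < maf_min]:
                drops.setdefault(vid, "maf")

    keep = [vid for vid in shared if vid not in drops]
    out_tables = []
    for t, frame in zip(tables, frames):
        rec = frame.loc[keep].reset_index(drop=True)
        out_tables.append(SumstatsTable(t.trait_label, rec, t.phenotype_variance))
    dropped_log = pd.DataFrame(
        sorted(drops.items()), columns=["variant_id", "reason"]
    )
    return HarmonizedSet(out_tables, dropped_log)


def read_ldscores(path, m: int | None = None, column_map: dict | None = None) -> LDScorePanel:
    """Read an LD-score panel (variant_id, ld_score[, weight]) from text.

    ``m`` is the genome-wide variant count used to scale the LD score
    regression slope; it defaults to the number of variants in the file.
    """
    raw = pd.read_csv(path, sep=r"\s+", compression="infer")
    column_map = dict(column_map or {})
    cols = {}
    for std in ("variant_id", "ld_score", "weight"):
        name = column_map.get(std, std)
        if name in raw.columns:
            cols[std] = name
    for std in ("variant_id", "ld_score"):
        if std not in cols:
            raise ConfigurationError(f"LD-score file missing column {std!r}")
    df = pd.DataFrame({std: raw[name] for std, name in cols.items()})
    df["variant_id"] = df["variant_id"].astype(str)
    df["ld_score"] = pd.to_numeric(df["ld_score"], errors="coerce")
    df = df[np.isfinite(df["ld_score"])].reset_index(drop=True)
    if df.empty:
        raise InputError(f"no parseable LD scores in {path}")
    return LDScorePanel(df, int(m) if m is not None else len(df))


def write_ldscores(panel: LDScorePanel, path) -> None:
    panel.records.to_csv(path, sep="\t", index=False)
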