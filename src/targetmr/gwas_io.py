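"""Reading, validation, windowing and harmonization of GWAS summary statistics.

Variant identity throughout the pipeline is ``chrom:pos`` plus the unordered
allele pair; rsIDs are carried for reporting but never used for matching.
Coordinates are 1-based and windows are inclusive on both ends.  Genome build
is a mandatory declared label on every table and no liftover is attempted:
mixing builds is an error, not a warning.

Harmonization aligns an outcome table to the exposure's effect alleles,
flipping outcome beta signs (and complementing frequencies) when the outcome
lists the allele pair in swapped order, and resolving strand-complemented
records.  Palindromic variants (A/T or C/G) are inherently strand-ambiguous;
they are resolved by effect-allele-frequency concordance when both
frequencies are far enough from 0.5, and dropped otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order of the internal summary-statistics frame
SUMMARY_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]


@dataclass(frozen=True)
class ExclusionRecord:
    """One dropped unit (variant, row, trial) with the stage and reason."""

    key: str
    stage: str
    reason: str


def write_exclusions(records: list[ExclusionRecord], path) -> None:
    """Write exclusion records to a machine-readable tab-delimited file."""
    pd.DataFrame(
        [(r.key, r.stage, r.reason) for r in records],
        columns=["key", "stage", "reason"],
    ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class CisWindow:
    """A genomic interval (1-based, inclusive on both bounds) on one build."""

    chrom: str
    start: int
    end: int
    build: str = "GRCh38"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"window start {self.start} must precede end {self.end}")


# The cis regions used for the two worked drug targets (GRCh38).
CETP_WINDOW = CisWindow(chrom="16", start=56_961_923, end=56_985_845, build="GRCh38")
PCSK9_WINDOW = CisWindow(chrom="1", start=55_037_447, end=55_066_852, build="GRCh38")


@dataclass
class SummaryTable:
    """Per-variant association records for one trait.

    ``df`` has the columns in :data:`SUMMARY_COLUMNS`; ``eaf`` and ``n`` may
    be NaN.  ``exclusions`` records rows rejected while building the table.
    """

    trait_name: str
    trait_type: str  # "continuous" | "binary"
    unit: str
    build: str
    df: pd.DataFrame
    exclusions: list[ExclusionRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def keys(self) -> pd.Series:
        return variant_keys(self.df)


def variant_keys(df: pd.DataFrame) -> pd.Series:
    """chrom:pos:allele-pair key; the allele pair is sorted so order-swapped
    records collide, which is what allows harmonization to find them."""
    a = df["effect_allele"].str.upper()
    b = df["other_allele"].str.upper()
    lo = np.where(a < b, a, b)
    hi = np.where(a < b, b, a)
    return (
        df["chrom"].astype(str) + ":" + df["pos"].astype(int).astype(str) + ":" + lo + "/" + hi
    )


def _complement(allele: str) -> str | None:
    try:
        return "".join(_COMPLEMENT[c] for c in allele.upper())
    except KeyError:
        return None


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    return _complement(effect_allele) == other_allele.upper()


def read_summary_stats(
    path,
    column_map: dict[str, str],
    trait_name: str = "trait",
    trait_type: str = "continuous",
    unit: str = "",
    build: str = "GRCh38",
    sep: str | None = None,
) -> SummaryTable:
    """Read a delimited summary-statistics file into a validated table.

    ``column_map`` maps internal field names (``variant_id``, ``chrom``,
    ``pos``, ``effect_allele``, ``other_allele``, ``beta``, ``se``,
    ``pvalue``; optionally ``eaf``, ``n``) to the file's column names.
    Rows violating the record invariants (non-positive SE, identical
    alleles, p outside (0, 1], eaf outside (0, 1), pos < 1, unparseable
    numerics) are dropped and logged, not fatal.  Duplicate variant keys
    keep the first occurrence.
    """
    mandatory = ["variant_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "pvalue"]
    missing = [f for f in mandatory if f not in column_map]
    if missing:
        raise KeyError(f"column_map missing mandatory fields: {missing}")

    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    raw = pd.read_csv(path, sep=sep, dtype=str)
    absent = [c for f, c in column_map.items() if c not in raw.columns]
    if absent:
        raise KeyError(f"file {path} lacks mapped columns: {absent}")

    df = pd.DataFrame({f: raw[c] for f, c in column_map.items()})
    for opt in ("eaf", "n"):
        if opt not in df.columns:
            df[opt] = np.nan

    exclusions: list[ExclusionRecord] = []
    if len(df) == 0:
        empty = pd.DataFrame(columns=SUMMARY_COLUMNS)
        return SummaryTable(trait_name, trait_type, unit, build, empty, exclusions)

    def _float(v):
        # python's strtod is correctly rounded; pandas' fast parser is not,
        # and round-tripping summary statistics must be exact
        try:
            return float(v)
        except (TypeError, ValueError):
            return np.nan

    for col in ("pos", "eaf", "beta", "se", "pvalue", "n"):
        df[col] = df[col].map(_float)
    df["chrom"] = df["chrom"].astype(str).str.removeprefix("chr")
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()

    numeric_ok = df[["pos", "beta", "se", "pvalue"]].notna().all(axis=1)
    valid = (
        numeric_ok
        & (df["se"] > 0)
        & (df["effect_allele"] != df["other_allele"])
        & (df["pvalue"] > 0)
        & (df["pvalue"] <= 1)
        & (df["pos"] >= 1)
        & (df["eaf"].isna() | ((df["eaf"] > 0) & (df["eaf"] < 1)))
    )
    for idx in df.index[~valid]:
        key = str(df.at[idx, "variant_id"])
        reason = "unparseable-numeric" if not numeric_ok[idx] else "invariant-violation"
        exclusions.append(ExclusionRecord(key, "read", reason))
    df = df[valid].copy()
    df["pos"] = df["pos"].astype(int)

    keys = variant_keys(df)
    dup = keys.duplicated(keep="first")
    for key in keys[dup]:
        exclusions.append(ExclusionRecord(key, "read", "duplicate-key"))
    df = df[~dup]

    df = df[SUMMARY_COLUMNS].reset_index(drop=True)
    return SummaryTable(trait_name, trait_type, unit, build, df, exclusions)


def write_summary_stats(table: SummaryTable, path, sep: str = "\t") -> None:
    """Write a table in the same dialect :func:`read_summary_stats` reads.

    Floats are written in shortest round-trip form so a read-back
    reproduces every numeric field exactly.
    """
    table.df.to_csv(path, sep=sep, index=False)


def extract_cis_window(table: SummaryTable, window: CisWindow) -> SummaryTable:
    """Restrict a table to the cis window (both bounds inclusive)."""
    if table.build != window.build:
        raise ValueError(
            f"build mismatch: table is {table.build}, window is {window.build}; "
            "no liftover is performed"
        )
    mask = (
        (table.df["chrom"].astype(str) == str(window.chrom))
        & (table.df["pos"] >= window.start)
        & (table.df["pos"] <= window.end)
    )
    return replace(table, df=table.df[mask].reset_index(drop=True), exclusions=list(table.exclusions))


@dataclass
class HarmonizedPairs:
    """Exposure/outcome associations joined on a common effect allele.

    ``df`` columns: key, variant_id, chrom, pos, effect_allele, other_allele,
    eaf (exposure), b_x, s_x, p_x, b_y, s_y, p_y, eaf_y, action.
    """

    df: pd.DataFrame
    exposure_name: str
    outcome_name: str
    exposure_unit: str
    outcome_unit: str
    outcome_type: str
    exclusions: list[ExclusionRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def keys(self) -> list[str]:
        return list(self.df["key"])


def harmonize(
    exposure: SummaryTable,
    outcome: SummaryTable,
    palindrome_eaf_limit: float = 0.42,
    drop_palindromic: bool = False,
) -> HarmonizedPairs:
    """Align outcome records to the exposure's effect alleles.

    Matching is by chrom:pos:unordered-allele-pair; when direct alleles do
    not correspond the outcome record is strand-complemented and retried.
    Swapped allele order negates the outcome beta and complements its EAF.
    Palindromic variants are kept only when both EAFs lie outside
    ``(limit, 1 - limit)``; their orientation is then inferred from EAF
    concordance (both frequencies on the same side of 0.5 means the listed
    effect alleles agree).  ``drop_palindromic`` is the strict mode that
    discards them unconditionally.
    """
    if exposure.build != outcome.build:
        raise ValueError(f"build mismatch: {exposure.build} vs {outcome.build}")
    lim = palindrome_eaf_limit

    exp = exposure.df.copy()
    exp["key"] = variant_keys(exp)
    out = outcome.df.copy()
    out["key"] = variant_keys(out)
    out_by_key = {k: row for k, row in zip(out["key"], out.itertuples(index=False))}
    # complement-keyed lookup catches records reported on the opposite strand
    comp_by_key: dict[str, tuple] = {}
    for row in out.itertuples(index=False):
        ea, oa = _complement(row.effect_allele), _complement(row.other_allele)
        if ea is not None and oa is not None and ea != oa:
            lo, hi = sorted((ea, oa))
            comp_by_key[f"{row.chrom}:{row.pos}:{lo}/{hi}"] = (row, ea, oa)

    rows = []
    exclusions: list[ExclusionRecord] = []
    for e in exp.itertuples(index=False):
        o = out_by_key.get(e.key)
        action = None
        if o is not None:
            o_ea, o_oa = o.effect_allele, o.other_allele
        elif e.key in comp_by_key:
            o, o_ea, o_oa = comp_by_key[e.key]
            action = "strand-complemented"
        else:
            exclusions.append(ExclusionRecord(e.key, "harmonize", "dropped-unmatched"))
            continue

        b_y, eaf_y = o.beta, o.eaf
        if is_palindromic(e.effect_allele, e.other_allele):
            if drop_palindromic or _pal_ambiguous(e.eaf, o.eaf, lim):
                exclusions.append(ExclusionRecord(e.key, "harmonize", "dropped-palindromic"))
                continue
            # orientation from frequency concordance: discordant sides of 0.5
            # mean the outcome's listed effect allele is the exposure's other
            same_side = (e.eaf < 0.5) == (o.eaf < 0.5)
            aligned = o_ea == e.effect_allele
            if same_side != aligned:
                b_y, eaf_y = -b_y, 1.0 - eaf_y
                action = "sign-flipped"
            elif action is None:
                action = "kept-as-is"
        elif (o_ea, o_oa) == (e.effect_allele, e.other_allele):
            action = action or "kept-as-is"
        elif (o_ea, o_oa) == (e.other_allele, e.effect_allele):
            b_y = -b_y
            eaf_y = 1.0 - eaf_y if not _isnan(eaf_y) else eaf_y
            action = "sign-flipped" if action is None else action
        else:
            exclusions.append(ExclusionRecord(e.key, "harmonize", "dropped-unmatched"))
            continue

        rows.append(
            (e.key, e.variant_id, e.chrom, e.pos, e.effect_allele, e.other_allele,
             e.eaf, e.beta, e.se, e.pvalue, b_y, o.se, o.pvalue, eaf_y, action)
        )

    df = pd.DataFrame(
        rows,
        columns=["key", "variant_id", "chrom", "pos", "effect_allele", "other_allele",
                 "eaf", "b_x", "s_x", "p_x", "b_y", "s_y", "p_y", "eaf_y", "action"],
    )
    return HarmonizedPairs(
        df=df,
        exposure_name=exposure.trait_name,
        outcome_name=outcome.trait_name,
        exposure_unit=exposure.unit,
        outcome_unit=outcome.unit,
        outcome_type=outcome.trait_type,
        exclusions=exclusions,
    )


def _isnan(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def _pal_ambiguous(eaf_x, eaf_y, lim: float) -> bool:
    """A palindromic variant is unresolvable when either EAF is missing or
    too close to 0.5 to pin the strand."""
    if _isnan(eaf_x) or _isnan(eaf_y):
        return True
    return (lim < eaf_x < 1 - lim) or (lim < eaf_y < 1 - lim)


def swap_alleles(record: pd.Series) -> pd.Series:
    """Re-express a summary record on the opposite effect allele.

    Swaps the allele labels, negates beta and complements the EAF; applying
    it twice is the identity.
    """
    r = record.copy()
    r["effect_allele"], r["other_allele"] = record["other_allele"], record["effect_allele"]
    r["beta"] = -record["beta"]
    if not _isnan(record.get("eaf", np.nan)):
        r["eaf"] = 1.0 - record["eaf"]
    return r
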