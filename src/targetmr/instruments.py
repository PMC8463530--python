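"""Instrument selection: MAF and F filters, reference-panel LD, greedy clumping.

The instrument-strength statistic is the per-variant squared Wald ratio
F = (beta/se)^2 on the exposure association; the default threshold of 15
limits weak-instrument bias in the two-sample design.  Clumping greedily
thins variants ranked by association p-value so that no retained pair
exceeds an r-squared ceiling (default 0.40); the LD matrix stores *signed*
correlations oriented to the harmonized effect alleles — clumping consumes
r^2, GLS estimation consumes the signed matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from targetmr.gwas_io import ExclusionRecord, HarmonizedPairs


@dataclass
class LDMatrix:
    """Signed Pearson correlation among instrument variants.

    Symmetric with unit diagonal; entries oriented to the harmonized effect
    alleles so that the sign convention matches the beta vectors.
    """

    variant_keys: list[str]
    r: np.ndarray

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.variant_keys)
        if self.r.shape != (m, m):
            raise ValueError(f"LD matrix shape {self.r.shape} does not match {m} keys")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("LD matrix must have unit diagonal")
        if np.any(np.abs(self.r) > 1 + 1e-10):
            raise ValueError("LD entries must lie in [-1, 1]")

    def subset(self, keys: list[str]) -> "LDMatrix":
        idx = [self.variant_keys.index(k) for k in keys]
        return LDMatrix(list(keys), self.r[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.variant_keys, columns=self.variant_keys)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LDMatrix":
        return cls(list(df.columns), df.to_numpy(dtype=float))


def nearest_psd(r: np.ndarray, tol: float = 1e-8) -> tuple[np.ndarray, float]:
    """Floor negative eigenvalues at zero and restore the unit diagonal.

    Returns the repaired matrix and the magnitude of the most negative
    eigenvalue that was floored (0.0 when no repair was needed).
    """
    w, v = np.linalg.eigh(np.asarray(r, dtype=float))
    if w.min() >= -tol:
        return np.asarray(r, dtype=float), 0.0
    repaired = (v * np.clip(w, 0.0, None)) @ v.T
    d = np.sqrt(np.clip(np.diag(repaired), tol, None))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    repaired = (repaired + repaired.T) / 2
    return repaired, float(-w.min())


def ld_from_reference(
    dosages: pd.DataFrame | np.ndarray,
    variant_keys: list[str] | None = None,
    flip: np.ndarray | None = None,
) -> LDMatrix:
    """Estimate signed LD from a reference dosage panel.

    ``dosages`` is individuals x variants with effect-allele dosages in
    [0, 2] (a DataFrame's columns supply the variant keys).  ``flip`` marks
    variants whose panel effect allele differs from the harmonized effect
    allele; their dosages are reflected (d -> 2 - d) before correlation, which
    negates the affected off-diagonal signs.  The result is repaired to the
    nearest non-negative-definite correlation matrix when sampling noise
    pushes an eigenvalue below zero.
    """
    if isinstance(dosages, pd.DataFrame):
        if variant_keys is None:
            variant_keys = list(dosages.columns)
        x = dosages.to_numpy(dtype=float)
    else:
        x = np.asarray(dosages, dtype=float)
        if variant_keys is None:
            raise ValueError("variant_keys required when dosages is a bare array")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 reference individuals")
    if x.shape[1] != len(variant_keys):
        raise ValueError("dosage columns do not match variant_keys")

    sd = x.std(axis=0)
    for j in np.flatnonzero(sd == 0):
        raise ValueError(f"zero-variance dosage column for variant {variant_keys[j]}")
    if flip is not None:
        x = x.copy()
        x[:, np.asarray(flip, dtype=bool)] = 2.0 - x[:, np.asarray(flip, dtype=bool)]

    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    r, repair = nearest_psd(r)
    if repair > 0:
        warnings.warn(f"LD matrix repaired to PSD (floored eigenvalue magnitude {repair:.3g})")
    return LDMatrix(list(variant_keys), r)


@dataclass
class InstrumentSet:
    """Post-filter, post-clump instruments with their LD submatrix.

    ``pairs`` rows and ``ld.variant_keys`` are in identical order; the
    filter log carries exactly one removal reason per dropped variant
    (the first failing filter).
    """

    pairs: HarmonizedPairs
    ld: LDMatrix
    f_stats: pd.Series
    filter_log: list[ExclusionRecord] = field(default_factory=list)

    def __post_init__(self):
        if list(self.pairs.df["key"]) != list(self.ld.variant_keys):
            raise ValueError("LD keys must match pair order exactly")

    def __len__(self) -> int:
        return len(self.pairs)


def dosages_from_vcf(path, region: str | None = None) -> pd.DataFrame:
    """Read effect-allele (ALT) dosages from a VCF into a reference panel.

    Returns individuals x variants with columns keyed chrom:pos:allele-pair
    (matching the pipeline's variant identity).  Genotypes are counted as
    ALT-allele copies; missing calls become the variant's mean dosage.
    Multi-allelic records are skipped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    cols: dict[str, np.ndarray] = {}
    for rec in vcf(region) if region else vcf:
        if len(rec.ALT) != 1:
            continue
        ref, alt = rec.REF.upper(), rec.ALT[0].upper()
        lo, hi = sorted((ref, alt))
        key = f"{str(rec.CHROM).removeprefix('chr')}:{rec.POS}:{lo}/{hi}"
        gt = np.asarray(rec.gt_types, dtype=float)  # 0=hom-ref,1=het,2=unknown,3=hom-alt
        d = np.where(gt == 3, 2.0, np.where(gt == 1, 1.0, np.where(gt == 0, 0.0, np.nan)))
        if np.isnan(d).all():
            continue
        d = np.where(np.isnan(d), np.nanmean(d), d)
        cols[key] = d
    return pd.DataFrame(cols)


def write_instrument_set(inst: "InstrumentSet", pairs_path, ld_path) -> None:
    """Serialize an instrument set as a pairs table plus a keyed LD matrix,
    both tab-delimited."""
    inst.pairs.df.to_csv(pairs_path, sep="\t", index=False)
    inst.ld.to_frame().to_csv(ld_path, sep="\t", index=True, index_label="key")


def read_instrument_ld(ld_path) -> LDMatrix:
    """Read back an LD matrix written by :func:`write_instrument_set`."""
    df = pd.read_csv(ld_path, sep="\t", index_col="key")
    return LDMatrix.from_frame(df)


def f_statistic(pairs: HarmonizedPairs) -> pd.Series:
    """Per-variant instrument strength: the squared Wald ratio (b_x/s_x)^2."""
    return (pairs.df["b_x"] / pairs.df["s_x"]) ** 2


def apply_instrument_filters(
    pairs: HarmonizedPairs,
    maf_min: float = 0.01,
    f_min: float = 15.0,
) -> HarmonizedPairs:
    """Drop variants failing the MAF or instrument-strength thresholds.

    MAF uses the exposure effect-allele frequency, min(eaf, 1 - eaf).
    Membership is order-insensitive; the logged reason is the first failing
    filter (MAF before F).
    """
    df = pairs.df
    if maf_min > 0 and df["eaf"].isna().any():
        raise ValueError("maf_min > 0 requires exposure EAF for every variant")
    maf_ok = (
        np.minimum(df["eaf"], 1 - df["eaf"]) >= maf_min
        if maf_min > 0
        else pd.Series(True, index=df.index)
    )
    f = f_statistic(pairs)
    f_ok = f >= f_min
    exclusions = list(pairs.exclusions)
    for i in df.index:
        if not maf_ok[i]:
            exclusions.append(ExclusionRecord(df.at[i, "key"], "filter", "maf_fail"))
        elif not f_ok[i]:
            exclusions.append(ExclusionRecord(df.at[i, "key"], "filter", "f_fail"))
    kept = df[maf_ok & f_ok].reset_index(drop=True)
    return replace(pairs, df=kept, exclusions=exclusions)


def greedy_clump(
    pairs: HarmonizedPairs,
    ld: LDMatrix,
    r2_max: float = 0.40,
    rank_by: str = "p_x",
) -> InstrumentSet:
    """Greedy LD clumping at an r-squared ceiling.

    Variants are ranked by ``rank_by`` p-value ascending (ties broken by
    smaller position); the top remaining variant is kept and every other
    variant with r^2 strictly above ``r2_max`` against *any* kept variant is
    removed.  r^2 exactly equal to the ceiling is retained.  The output is
    invariant to input row order.
    """
    if not (0 < r2_max <= 1):
        raise ValueError("r2_max must be in (0, 1]")
    df = pairs.df
    if len(df) == 0:
        return InstrumentSet(pairs, LDMatrix([], np.zeros((0, 0))), pd.Series(dtype=float))
    missing = [k for k in df["key"] if k not in ld.variant_keys]
    if missing:
        raise ValueError(f"LD matrix lacks variants: {missing[:5]}")

    sub = ld.subset(list(df["key"]))
    r2 = sub.r ** 2
    order = df.sort_values(["{0}".format(rank_by), "pos"], kind="mergesort").index.to_numpy()

    kept: list[int] = []
    removed: dict[int, str] = {}
    for i in order:
        ii = df.index.get_loc(i)
        if ii in removed:
            continue
        kept.append(ii)
        for jj in range(len(df)):
            if jj != ii and jj not in removed and not any(jj == k for k in kept):
                if r2[ii, jj] > r2_max:
                    removed[jj] = df.at[df.index[jj], "key"]

    kept_positional = sorted(kept)  # preserve genomic/table order in output
    exclusions = list(pairs.exclusions)
    for jj, key in removed.items():
        exclusions.append(ExclusionRecord(key, "clump", "clump_removed"))
    kept_df = df.iloc[kept_positional].reset_index(drop=True)
    kept_pairs = replace(pairs, df=kept_df, exclusions=exclusions)
    kept_ld = sub.subset(list(kept_df["key"]))

    # hard invariant: no surviving pair exceeds the ceiling
    off = kept_ld.r ** 2 - np.eye(len(kept_df))
    assert off.max(initial=0.0) <= r2_max + 1e-12, "clumping left a pair above r2_max"

    return InstrumentSet(
        pairs=kept_pairs,
        ld=kept_ld,
        f_stats=f_statistic(kept_pairs),
        filter_log=[e for e in exclusions if e.stage in ("filter", "clump")],
    )
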