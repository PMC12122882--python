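"""Bulk whole-genome substitution post-processing and burden estimation.

Bulk sequencing observes each site as a pool of reads drawn from all cells in
the sample, so a mutation is detectable only when the carrying cell fraction
is large enough for several mutant reads to appear at the sequenced depth.
This module implements the post-processing applied to bulk substitution
calls -- alignment-quality filtering, the organoid in-vitro VAF filter,
hypergeometric downsampling to a reference coverage -- and the bulk burden
estimate, which is simply the count of passing substitution records.  Under a
comb-like (short-trunk, polyclonal) architecture that count understates the
true per-cell burden: that understatement is the artefact this package
quantifies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .duplex_burden import BurdenEstimate, garwood_interval

__all__ = [
    "VariantTable",
    "qc_filter",
    "organoid_vaf_filter",
    "downsample_to_depth",
    "bulk_burden",
    "is_called",
]

#: Columns every VariantTable carries (one row per site x sample).
CORE_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "sample",
    "depth",
    "alt_fwd",
    "alt_rev",
    "median_alignment_score",
    "clipped_fraction",
]


@dataclass
class VariantTable:
    """Multi-sample substitution records with per-sample strand-resolved counts.

    ``df`` holds one row per (site, sample) with the :data:`CORE_COLUMNS`
    (plus optional provenance / ground-truth columns).  ``sample_class`` maps
    each sample to ``"tissue"``, ``"organoid"`` or ``"normal"``;
    ``calling_mode`` records whether calls came from matched or unmatched
    calling.  ``filter_log`` accumulates (filter name, records removed) pairs
    so that statements like "4% of mutations were removed" are recomputable
    from any run.
    """

    df: pd.DataFrame
    sample_class: dict[str, str] = field(default_factory=dict)
    calling_mode: str = "matched"
    filter_log: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in CORE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")
        alt = self.df["alt_fwd"] + self.df["alt_rev"]
        if (alt > self.df["depth"]).any():
            raise ValueError("mutant reads exceed depth")

    # -- convenience accessors ------------------------------------------------

    @property
    def alt_total(self) -> pd.Series:
        return self.df["alt_fwd"] + self.df["alt_rev"]

    @property
    def vaf(self) -> pd.Series:
        depth = self.df["depth"].replace(0, np.nan)
        return (self.alt_total / depth).fillna(0.0)

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample"].unique())

    def site_keys(self) -> pd.DataFrame:
        return self.df[["chrom", "pos", "ref", "alt"]].drop_duplicates()

    @property
    def n_sites(self) -> int:
        return len(self.site_keys())

    def with_df(self, df: pd.DataFrame, log_entry: tuple[str, int] | None = None) -> "VariantTable":
        log = list(self.filter_log) + ([log_entry] if log_entry else [])
        return replace(self, df=df.reset_index(drop=True), filter_log=log)

    def for_sample(self, sample: str) -> pd.DataFrame:
        return self.df[self.df["sample"] == sample]


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def qc_filter(
    table: VariantTable, min_alignment_score: float = 140.0, max_clipped_fraction: float = 0.5
) -> VariantTable:
    """Remove records with poorly aligned supporting reads.

    A record is kept iff the median alignment score of its supporting reads
    is >= 140 and fewer than half of those reads are clipped.  Records with no
    mutant reads have no supporting reads and pass vacuously (they encode the
    *absence* of a mutation in one sample, which downstream multi-sample
    genotyping needs).
    """
    for col in ("median_alignment_score", "clipped_fraction"):
        if table.df[col].isna().any():
            raise ValueError(f"missing QC annotation {col!r}")
    alt = table.alt_total
    keep = (alt == 0) | (
        (table.df["median_alignment_score"] >= min_alignment_score)
        & (table.df["clipped_fraction"] < max_clipped_fraction)
    )
    return table.with_df(table.df[keep], ("qc_filter", int((~keep).sum())))


def organoid_vaf_filter(table: VariantTable, min_vaf: float = 0.3) -> VariantTable:
    """Drop sub-clonal records in single-cell-derived organoid samples.

    An organoid grown from one cell should carry its founder's mutations near
    VAF 0.5; mutations acquired in vitro appear at lower fractions.  Only
    records with VAF strictly greater than ``min_vaf`` are kept.  Raises if
    the table contains no organoid-class samples.
    """
    organoids = {s for s, c in table.sample_class.items() if c == "organoid"}
    if not organoids:
        raise ValueError("organoid_vaf_filter applied to a table with no organoid samples")
    is_org = table.df["sample"].isin(organoids)
    keep = ~is_org | (table.vaf > min_vaf)
    return table.with_df(table.df[keep], ("organoid_vaf_filter", int((~keep).sum())))


def downsample_to_depth(table: VariantTable, target_depth: float, seed: int) -> VariantTable:
    """Thin each sample's reads to a target mean coverage.

    Mirrors BAM downsampling: each sample is thinned by the ratio
    ``target / mean depth``; per record the retained total depth is binomial
    in that ratio and the retained mutant reads (and their strand split) are
    hypergeometric draws from the finite read pool.  Samples already at or
    below the target pass through unchanged with a warning.
    """
    if target_depth <= 0:
        raise ValueError("target depth must be positive")
    rng = np.random.default_rng(seed)
    out = table.df.copy()
    for sample in table.samples:
        mask = (out["sample"] == sample).to_numpy()
        depth = out.loc[mask, "depth"].to_numpy()
        mean_depth = depth.mean() if depth.size else 0.0
        if mean_depth <= target_depth:
            if mean_depth < target_depth:
                warnings.warn(
                    f"sample {sample!r} mean depth {mean_depth:.1f} below target {target_depth}; left unchanged",
                    stacklevel=2,
                )
            continue
        ratio = target_depth / mean_depth
        alt_f = out.loc[mask, "alt_fwd"].to_numpy()
        alt_r = out.loc[mask, "alt_rev"].to_numpy()
        alt = alt_f + alt_r
        new_depth = rng.binomial(depth, ratio)
        new_alt = rng.hypergeometric(alt, depth - alt, new_depth)
        new_fwd = rng.hypergeometric(alt_f, alt_r, new_alt)
        out.loc[mask, "depth"] = new_depth
        out.loc[mask, "alt_fwd"] = new_fwd
        out.loc[mask, "alt_rev"] = new_alt - new_fwd
    return table.with_df(out)


# ---------------------------------------------------------------------------
# Burden
# ---------------------------------------------------------------------------


def is_called(
    df: pd.DataFrame, min_alt_reads: int = 4, require_both_strands: bool = True
) -> pd.Series:
    """Transparent stand-in for a probabilistic caller's decision on simulated data.

    A substitution counts as bulk-called in a sample when it is supported by
    at least ``min_alt_reads`` mutant reads, on both strands if required.
    """
    alt = df["alt_fwd"] + df["alt_rev"]
    called = alt >= min_alt_reads
    if require_both_strands:
        called &= (df["alt_fwd"] >= 1) & (df["alt_rev"] >= 1)
    return called


def bulk_burden(
    table: VariantTable,
    sample: str | None = None,
    min_alt_reads: int = 4,
    require_both_strands: bool = True,
) -> BurdenEstimate:
    """Bulk burden = number of passing substitution records in a sample.

    With several samples and no ``sample`` given, the median per-sample count
    is reported (the convention used when a tumour is represented by multiple
    biopsies).  The Poisson interval reflects counting uncertainty only.
    """
    df = table.df
    normals = {s for s, c in table.sample_class.items() if c == "normal"}
    if sample is not None:
        counts = [int(is_called(table.for_sample(sample), min_alt_reads, require_both_strands).sum())]
        mean_depth = table.for_sample(sample)["depth"].mean()
    else:
        tumour = df[~df["sample"].isin(normals)]
        counts = [
            int(is_called(g, min_alt_reads, require_both_strands).sum())
            for _, g in tumour.groupby("sample", sort=True)
        ] or [0]
        mean_depth = tumour["depth"].mean() if len(tumour) else float("nan")
    value = float(np.median(counts))
    lo, hi = garwood_interval(int(round(value)))
    return BurdenEstimate(
        mutations_per_diploid_genome=value,
        method="bulk",
        n_calls=int(round(value)),
        ci95=(min(lo, value), max(hi, value)),
        effective_coverage=float(mean_depth) if mean_depth == mean_depth else None,
        sample=sample,
    )
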