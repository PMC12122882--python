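"""Rule-based driver-mutation annotation.

Implements a curated driver-calling rule set over small variants,
copy-number segments, structural rearrangements and expression, of the kind
used in paediatric tumour genomics:

* missense / in-frame variants at canonical hotspot codons of oncogenes;
* truncating variants disrupting the footprint of recessive cancer genes;
* manual rescue of promoter hotspot sites (e.g. TERT) that standard callers
  reject for lying in simple repeats;
* focal (<1 Mb) homozygous deletions over recessive genes and focal
  amplifications over oncogenes exceeding a ploidy-dependent copy-number
  threshold (>4 diploid, >8 tetraploid), with sub-threshold amplifications
  admitted only when RNA expression is significantly elevated (z-score);
* rearrangements producing whitelisted fusions, disrupting recessive gene
  footprints, or juxtaposing an oncogene's regulatory domain to an active
  promoter with elevated expression (the FOXR2-type promoter-swap event).

Every call cites exactly one rule, and call lists are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .bulk_burden import VariantTable
from .phylogeny import CopyNumberProfile, MutationTree

__all__ = [
    "GeneModel",
    "DriverCall",
    "load_gene_models",
    "bundled_gene_models",
    "annotate_small_variants",
    "rescue_promoter_sites",
    "annotate_copy_number",
    "annotate_rearrangements",
    "assign_clonality",
]

TRUNCATING = {"stop_gained", "frameshift", "splice_donor", "splice_acceptor", "nonsense"}
HOTSPOT_CONSEQUENCES = {"missense", "inframe_deletion", "inframe_insertion"}

FOCAL_MAX_BP = 1_000_000
AMP_THRESHOLD = {"diploid": 4, "tetraploid": 8}
DEFAULT_Z_CUTOFF = 2.0


@dataclass(frozen=True)
class GeneModel:
    """A cancer gene's footprint and role for the rule engine."""

    symbol: str
    role: str  # "oncogene" | "recessive"
    chrom: str
    start: int  # 0-based half-open footprint
    end: int
    hotspot_codons: tuple[int, ...] = ()
    regulatory_start: int | None = None
    regulatory_end: int | None = None

    def __post_init__(self) -> None:
        if self.role not in ("oncogene", "recessive"):
            raise ValueError(f"unknown gene role {self.role!r}")
        if self.end <= self.start:
            raise ValueError("invalid gene footprint")

    def footprint_contains(self, chrom: str, pos0: int) -> bool:
        return chrom == self.chrom and self.start <= pos0 < self.end

    def regulatory_contains(self, chrom: str, pos0: int) -> bool:
        if self.regulatory_start is None or self.regulatory_end is None:
            return False
        return chrom == self.chrom and self.regulatory_start <= pos0 < self.regulatory_end


@dataclass(frozen=True)
class DriverCall:
    gene: str
    event_class: str
    rule: str
    clonality: str | None = None  # "clonal" | "subclonal" | None (unresolved)
    detail: str = ""


def load_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from a TSV (symbol, role, chrom, start, end,
    hotspot_codons as comma-separated integers, regulatory_start/end)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for row in df.itertuples(index=False):
        hotspots = ()
        if isinstance(row.hotspot_codons, str) and row.hotspot_codons:
            hotspots = tuple(int(x) for x in row.hotspot_codons.split(","))
        reg_s = None if pd.isna(row.regulatory_start) else int(row.regulatory_start)
        reg_e = None if pd.isna(row.regulatory_end) else int(row.regulatory_end)
        out.append(
            GeneModel(
                symbol=row.symbol,
                role=row.role,
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                hotspot_codons=hotspots,
                regulatory_start=reg_s,
                regulatory_end=reg_e,
            )
        )
    return out


def bundled_gene_models() -> list[GeneModel]:
    """The small illustrative gene list shipped with the package.

    Coordinates and hotspot codons are synthetic stand-ins (full curated
    cancer-gene censuses are licensed); the list exists to exercise every
    rule, not to annotate real data.
    """
    with resources.as_file(resources.files("clonarch.data") / "driver_genes_synthetic.tsv") as p:
        return load_gene_models(p)


def _by_symbol(genes: list[GeneModel]) -> dict[str, GeneModel]:
    return {g.symbol: g for g in genes}


def annotate_small_variants(variants: pd.DataFrame, genes: list[GeneModel]) -> list[DriverCall]:
    """Driver calls from consequence-annotated small variants.

    ``variants`` needs columns gene, consequence and (for hotspot matching)
    codon.  Hotspot missense / in-frame events in oncogenes and truncating
    events in recessive gene footprints are emitted; everything else is
    ignored.  Consequence annotation is an input requirement, not computed
    here.
    """
    if "consequence" not in variants.columns or variants["consequence"].isna().any():
        raise ValueError("variants must carry consequence annotations")
    models = _by_symbol(genes)
    calls: list[DriverCall] = []
    for row in variants.itertuples(index=False):
        gene = models.get(row.gene)
        if gene is None:
            continue
        csq = row.consequence
        if gene.role == "oncogene" and csq in HOTSPOT_CONSEQUENCES:
            codon = getattr(row, "codon", None)
            if codon is not None and not pd.isna(codon) and int(codon) in gene.hotspot_codons:
                calls.append(
                    DriverCall(gene.symbol, "hotspot_missense", rule="oncogene_hotspot",
                               detail=f"codon {int(codon)}")
                )
        elif gene.role == "recessive" and csq in TRUNCATING:
            calls.append(DriverCall(gene.symbol, "truncating", rule="recessive_truncating", detail=csq))
    return sorted(calls, key=lambda c: (c.gene, c.event_class, c.detail))


def rescue_promoter_sites(
    table: VariantTable, rescue_sites: list[tuple[str, int]]
) -> VariantTable:
    """Reinstate filtered-out records at listed promoter hotspot sites.

    Promoter hotspots (canonically TERT) sit in simple repeats and fail
    standard caller filters; records at the listed (chrom, 1-based pos)
    sites whose FILTER status is not PASS are restored with a rescue flag.
    """
    df = table.df.copy()
    if "filter" not in df.columns:
        df["filter"] = "PASS"
    if "rescued" not in df.columns:
        df["rescued"] = False
    site_set = {(str(c), int(p)) for c, p in rescue_sites}
    if site_set:
        hit = df.apply(lambda r: (str(r["chrom"]), int(r["pos"])) in site_set, axis=1)
        to_rescue = hit & (df["filter"] != "PASS")
        df.loc[to_rescue, "filter"] = "PASS"
        df.loc[to_rescue, "rescued"] = True
    return table.with_df(df, ("rescue_promoter_sites", 0))


def annotate_copy_number(
    profiles: CopyNumberProfile,
    genes: list[GeneModel],
    ploidy: str = "diploid",
    expression_z: dict[str, float] | None = None,
    z_cutoff: float = DEFAULT_Z_CUTOFF,
) -> list[DriverCall]:
    """Driver calls from copy-number segments.

    Focal (<1 Mb) homozygous deletions over recessive genes and focal
    amplifications over oncogenes above the ploidy threshold (>4 diploid,
    >8 tetraploid) are drivers outright; focal amplifications above the
    sample ploidy but below the threshold require expression z >= ``z_cutoff``.
    """
    if ploidy not in AMP_THRESHOLD:
        raise ValueError(f"unknown ploidy {ploidy!r}")
    threshold = AMP_THRESHOLD[ploidy]
    base_cn = 2 if ploidy == "diploid" else 4
    expression_z = expression_z or {}
    calls: list[DriverCall] = []
    for row in profiles.df.itertuples(index=False):
        length = row.end - row.start
        focal = length < FOCAL_MAX_BP
        for gene in genes:
            overlaps = gene.chrom == str(row.chrom) and row.start < gene.end and gene.start < row.end
            if not overlaps or not focal:
                continue
            if gene.role == "recessive" and row.total_cn == 0:
                calls.append(
                    DriverCall(gene.symbol, "homozygous_deletion", rule="focal_homozygous_deletion",
                               detail=f"{row.sample}:{row.chrom}:{row.start}-{row.end}")
                )
            elif gene.role == "oncogene" and row.total_cn > threshold:
                calls.append(
                    DriverCall(gene.symbol, "amplification", rule="focal_amplification",
                               detail=f"{row.sample}:CN{row.total_cn}")
                )
            elif (
                gene.role == "oncogene"
                and base_cn < row.total_cn <= threshold
                and expression_z.get(gene.symbol, 0.0) >= z_cutoff
            ):
                calls.append(
                    DriverCall(gene.symbol, "sub_amplification_with_expression",
                               rule="sub_amplification_expression",
                               detail=f"{row.sample}:CN{row.total_cn}:z{expression_z[gene.symbol]:g}")
                )
    return sorted(set(calls), key=lambda c: (c.gene, c.event_class, c.detail))


def annotate_rearrangements(
    breakpoints: pd.DataFrame,
    genes: list[GeneModel],
    expression_z: dict[str, float] | None = None,
    fusion_whitelist: set[frozenset] | None = None,
    z_cutoff: float = DEFAULT_Z_CUTOFF,
) -> list[DriverCall]:
    """Driver calls from structural rearrangements.

    ``breakpoints`` needs columns chrom1, pos1, chrom2, pos2 (positions
    0-based) and optionally gene1/gene2 partner annotations.  Whitelisted
    fusions and recessive-footprint-disrupting breakpoints are drivers;
    rearrangements touching an oncogene's regulatory domain require elevated
    expression (z >= ``z_cutoff``) -- the promoter-swap mechanism by which
    FOXR2 is activated.
    """
    for col in ("chrom1", "pos1", "chrom2", "pos2"):
        if col not in breakpoints.columns:
            raise ValueError(f"malformed breakpoint table: missing {col}")
    expression_z = expression_z or {}
    fusion_whitelist = fusion_whitelist or set()
    calls: list[DriverCall] = []
    for row in breakpoints.itertuples(index=False):
        g1 = getattr(row, "gene1", None)
        g2 = getattr(row, "gene2", None)
        if g1 and g2 and frozenset((g1, g2)) in fusion_whitelist:
            calls.append(
                DriverCall("::".join(sorted((g1, g2))), "fusion", rule="whitelist_fusion",
                           detail=f"{row.chrom1}:{row.pos1}|{row.chrom2}:{row.pos2}")
            )
            continue
        ends = ((str(row.chrom1), int(row.pos1)), (str(row.chrom2), int(row.pos2)))
        for gene in genes:
            if gene.role == "recessive" and any(gene.footprint_contains(c, p) for c, p in ends):
                calls.append(
                    DriverCall(gene.symbol, "truncating", rule="recessive_footprint_breakpoint",
                               detail=f"{row.chrom1}:{row.pos1}|{row.chrom2}:{row.pos2}")
                )
            elif gene.role == "oncogene" and any(gene.regulatory_contains(c, p) for c, p in ends):
                if expression_z.get(gene.symbol, 0.0) >= z_cutoff:
                    calls.append(
                        DriverCall(gene.symbol, "regulatory_rearrangement",
                                   rule="regulatory_rearrangement_expression",
                                   detail=f"z{expression_z[gene.symbol]:g}")
                    )
    return sorted(set(calls), key=lambda c: (c.gene, c.event_class, c.detail))


def assign_clonality(
    calls: list[DriverCall], tree: MutationTree, mutation_branch: dict[str, str]
) -> list[DriverCall]:
    """Mark driver calls clonal (trunk) or subclonal from the phylogeny.

    ``mutation_branch`` maps a driver's mutation key (gene symbol here) to
    the branch it was assigned to; branches on the root-to-first-split path
    are clonal, everything else subclonal.
    """
    trunk: set[str] = set()
    node = tree.root
    while len(tree.nodes[node].children) == 1:
        node = tree.nodes[node].children[0]
        trunk.add(node)
    out = []
    for call in calls:
        branch = mutation_branch.get(call.gene)
        if branch is None:
            out.append(call)
        else:
            clonality = "clonal" if branch in trunk else "subclonal"
            out.append(DriverCall(call.gene, call.event_class, call.rule, clonality, call.detail))
    return out
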