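"""Tumour phylogeny construction from multi-sample substitution data.

The pipeline mirrors established somatic-phylogenetics practice for
laser-capture microbiopsies and single-cell-derived organoids, where each
sample is treated as a clonal unit:

1. a germline filter that removes variants consistent with heterozygosity in
   the matched normal *and* not enriched in the tumour -- deliberately
   retaining embryonic mosaic variants (low normal VAF, clonal in tumour);
2. an exact binomial test for forward/reverse strand imbalance;
3. a per-sample confidence requirement (>= 4 mutant reads, VAF >= 0.3, both
   strands) that each variant must meet somewhere;
4. exclusion of variants in regions whose copy-number state differs between
   samples (or, for heavily rearranged genomes, only deleted regions), with
   the excluded genome fraction retained for branch-length scaling;
5. maximum-parsimony tree building over clonal units (exhaustive for small
   instances, greedy perfect-phylogeny + NNI hill climbing otherwise),
   rooted by a zero-mutation outgroup representing the matched normal;
6. maximum-likelihood assignment of each mutation to a branch under a
   binomial read-count model, and scaling of branch lengths by
   1 / (1 - excluded genome fraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bulk_burden import VariantTable
from .genome import AUTOSOMES, GENOME_LENGTH

__all__ = [
    "CopyNumberProfile",
    "GenotypeMatrix",
    "MutationTree",
    "TreeNode",
    "filter_germline",
    "filter_strand_imbalance",
    "filter_confident_somewhere",
    "exclude_cn_discordant",
    "build_parsimony_tree",
    "assign_mutations_ml",
    "scale_branches",
    "parsimony_placement",
    "binomial_two_sided_pvalue",
    "binomial_enrichment_pvalue",
]

OUTGROUP = "normal_ancestor"


# ---------------------------------------------------------------------------
# Exact binomial tests (vectorised)
# ---------------------------------------------------------------------------


def binomial_two_sided_pvalue(k, n) -> np.ndarray:
    """Exact two-sided binomial test p-value against p = 1/2.

    Uses the symmetry of the null: the two-sided p-value is the probability
    of all outcomes at least as extreme as ``k`` in either tail, which for
    p = 1/2 equals 2 * P(X <= min(k, n - k)) capped at 1.  ``n = 0`` gives 1.
    """
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    m = np.minimum(k, n - k)
    with np.errstate(invalid="ignore"):
        p = 2 * stats.binom.cdf(m, np.maximum(n, 1), 0.5)
    p = np.where(n == 0, 1.0, np.minimum(p, 1.0))
    return p


def binomial_enrichment_pvalue(k_normal, n_normal, tumour_vaf) -> np.ndarray:
    """One-sided exact test that the tumour is enriched relative to the normal.

    Computes P(X <= k_normal | n_normal, tumour_vaf): the probability of
    matched-normal counts this low if the site's true VAF matched the pooled
    tumour VAF.  The null probability comes from the pooled tumour counts
    (many samples, hence well estimated) and the tail is evaluated on the
    shallow normal sample -- the stable direction for an exact plug-in test.
    A small p-value means the tumour is significantly enriched over the
    normal.
    """
    k = np.asarray(k_normal, dtype=np.int64)
    n = np.asarray(n_normal, dtype=np.int64)
    p0 = np.clip(np.asarray(tumour_vaf, dtype=float), 0.0, 1.0)
    p = stats.binom.cdf(k, np.maximum(n, 1), p0)
    return np.where(n == 0, 1.0, p)


# ---------------------------------------------------------------------------
# Copy-number profiles
# ---------------------------------------------------------------------------


@dataclass
class CopyNumberProfile:
    """Per-sample genome segmentation with total copy number.

    Segments are 0-based half-open and must tile each modelled chromosome
    without gaps or overlaps for every sample.
    """

    df: pd.DataFrame  # sample, chrom, start, end, total_cn

    def __post_init__(self) -> None:
        required = {"sample", "chrom", "start", "end", "total_cn"}
        if missing := required - set(self.df.columns):
            raise ValueError(f"copy-number table missing columns {sorted(missing)}")

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample"].unique())

    def validate_coverage(self) -> None:
        lengths = dict(AUTOSOMES)
        for (sample, chrom), g in self.df.groupby(["sample", "chrom"], sort=False):
            g = g.sort_values("start")
            if g["start"].iloc[0] != 0 or g["end"].iloc[-1] != lengths.get(chrom):
                raise ValueError(f"copy-number profile gap for {sample} on {chrom}")
            if (g["end"].to_numpy()[:-1] != g["start"].to_numpy()[1:]).any():
                raise ValueError(f"copy-number profile gap for {sample} on {chrom}")
        chroms = set(self.df["chrom"].unique())
        for sample in self.samples:
            if set(self.df.loc[self.df["sample"] == sample, "chrom"]) != chroms:
                raise ValueError(f"copy-number profile gap: {sample} misses chromosomes")


def exclude_cn_discordant(
    table: VariantTable,
    profiles: CopyNumberProfile,
    mode: str = "standard",
    ploidy: int = 2,
) -> tuple[VariantTable, float]:
    """Drop variants where the copy-number state is not comparable across samples.

    ``standard`` removes variants in any region whose total copy number is
    not identical across all profiled samples; ``deletion_only`` (for genomes
    where almost everything is discordant) removes variants only where some
    sample carries a deletion (total CN below ``ploidy``).  Returns the
    filtered table and the genomic fraction excluded, which downstream branch
    scaling divides out.
    """
    if mode not in ("standard", "deletion_only"):
        raise ValueError(f"unknown mode {mode!r}")
    profiles.validate_coverage()
    samples = profiles.samples
    discordant: dict[str, list[tuple[int, int]]] = {}
    excluded = 0
    for chrom, length in AUTOSOMES:
        sub = profiles.df[profiles.df["chrom"] == chrom]
        if sub.empty:
            raise ValueError(f"copy-number profile gap on {chrom}")
        cuts = np.unique(np.concatenate([sub["start"].to_numpy(), sub["end"].to_numpy()]))
        starts, ends = cuts[:-1], cuts[1:]
        cn = np.empty((len(samples), len(starts)), dtype=np.int64)
        for i, sample in enumerate(samples):
            g = sub[sub["sample"] == sample].sort_values("start")
            idx = np.searchsorted(g["start"].to_numpy(), starts, side="right") - 1
            cn[i] = g["total_cn"].to_numpy()[idx]
        if mode == "standard":
            bad = (cn != cn[0]).any(axis=0)
        else:
            bad = (cn < ploidy).any(axis=0)
        discordant[chrom] = [(int(s), int(e)) for s, e in zip(starts[bad], ends[bad])]
        excluded += int((ends[bad] - starts[bad]).sum())
    fraction = excluded / GENOME_LENGTH

    keep = np.ones(len(table.df), dtype=bool)
    pos0 = table.df["pos"].to_numpy() - 1  # variants are 1-based
    chroms = table.df["chrom"].to_numpy()
    for chrom, intervals in discordant.items():
        if not intervals:
            continue
        on_chrom = chroms == chrom
        for s, e in intervals:
            keep &= ~(on_chrom & (pos0 >= s) & (pos0 < e))
    removed = int((~keep).sum())
    return table.with_df(table.df[keep], ("exclude_cn_discordant", removed)), fraction


# ---------------------------------------------------------------------------
# Variant filters
# ---------------------------------------------------------------------------


def _site_key(df: pd.DataFrame) -> pd.Series:
    return (
        df["chrom"].astype(str)
        + ":"
        + df["pos"].astype(str)
        + ":"
        + df["ref"].astype(str)
        + ":"
        + df["alt"].astype(str)
    )


def _normal_samples(table: VariantTable) -> set[str]:
    return {s for s, c in table.sample_class.items() if c == "normal"}


def filter_germline(
    table: VariantTable,
    matched_normal: str = "normal",
    alpha_clonal: float = 0.01,
    alpha_enrich: float = 0.001,
) -> VariantTable:
    """Remove germline variants without removing embryonic mosaic mutations.

    A variant is removed iff (a) its matched-normal counts are consistent
    with clonal heterozygosity (exact binomial test against VAF 0.5 not
    rejected at ``alpha_clonal``) and (b) it is not significantly enriched in
    the pooled tumour samples relative to the matched normal (one-sided exact
    binomial at ``alpha_enrich``; see
    :func:`binomial_enrichment_pvalue`).  A mosaic variant at low VAF in the
    normal fails (a), and a variant absent from the normal fails (b), so
    both are retained.
    """
    if matched_normal not in set(table.df["sample"]):
        raise ValueError(f"matched normal {matched_normal!r} not in table")
    df = table.df.copy()
    key = _site_key(df)
    alt = (df["alt_fwd"] + df["alt_rev"]).to_numpy()
    is_norm = (df["sample"] == matched_normal).to_numpy()

    agg = pd.DataFrame({"key": key, "alt": alt, "depth": df["depth"].to_numpy(), "normal": is_norm})
    norm = agg[agg["normal"]].groupby("key")[["alt", "depth"]].sum()
    tum = agg[~agg["normal"]].groupby("key")[["alt", "depth"]].sum()
    sites = norm.join(tum, how="outer", lsuffix="_n", rsuffix="_t").fillna(0).astype(np.int64)

    clonal_p = binomial_two_sided_pvalue(sites["alt_n"], sites["depth_n"])
    tumour_vaf = np.where(
        sites["depth_t"] > 0, sites["alt_t"] / sites["depth_t"].replace(0, 1), 0.0
    )
    enrich_p = binomial_enrichment_pvalue(sites["alt_n"], sites["depth_n"], tumour_vaf)
    remove = (clonal_p >= alpha_clonal) & (enrich_p >= alpha_enrich) & (sites["depth_n"].to_numpy() > 0)
    removed_keys = set(sites.index[remove])
    keep = ~key.isin(removed_keys)
    n_sites_removed = len(removed_keys)
    return table.with_df(df[keep], ("filter_germline", n_sites_removed))


def filter_strand_imbalance(table: VariantTable, alpha: float = 0.001) -> VariantTable:
    """Remove variants whose mutant reads reject a symmetric strand split.

    Pooled forward/reverse mutant counts per site are tested with the exact
    two-sided binomial test against p = 1/2; sites with p < ``alpha`` are
    dropped.  Sites with too few mutant reads to reach significance are
    untestable and retained.
    """
    df = table.df
    key = _site_key(df)
    pooled = pd.DataFrame(
        {"key": key, "fwd": df["alt_fwd"].to_numpy(), "rev": df["alt_rev"].to_numpy()}
    ).groupby("key")[["fwd", "rev"]].sum()
    p = binomial_two_sided_pvalue(pooled["fwd"], pooled["fwd"] + pooled["rev"])
    removed_keys = set(pooled.index[p < alpha])
    keep = ~key.isin(removed_keys)
    return table.with_df(df[keep], ("filter_strand_imbalance", len(removed_keys)))


def filter_confident_somewhere(
    table: VariantTable, min_alt: int = 4, min_vaf: float = 0.3
) -> VariantTable:
    """Require each mutation to be confidently called in at least one sample.

    Confidence means >= ``min_alt`` mutant reads, VAF >= ``min_vaf`` and
    mutant reads on both strands, in at least one non-normal sample.
    """
    df = table.df
    key = _site_key(df)
    alt = df["alt_fwd"] + df["alt_rev"]
    vaf = alt / df["depth"].replace(0, np.nan)
    confident = (
        (alt >= min_alt)
        & (vaf.fillna(0) >= min_vaf)
        & (df["alt_fwd"] >= 1)
        & (df["alt_rev"] >= 1)
        & ~df["sample"].isin(_normal_samples(table))
    )
    good_keys = set(key[confident])
    keep = key.isin(good_keys)
    n_removed = key.nunique() - len(good_keys & set(key))
    return table.with_df(df[keep], ("filter_confident_somewhere", n_removed))


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Binary presence of each mutation in each clonal unit, with read counts.

    ``presence`` is units x mutations (bool), derived from the same
    confidence criteria used by :func:`filter_confident_somewhere`;
    ``alt``/``depth`` keep the underlying counts for likelihood work.
    """

    presence: pd.DataFrame
    alt: pd.DataFrame
    depth: pd.DataFrame

    @property
    def units(self) -> list[str]:
        return list(self.presence.index)

    @property
    def mutations(self) -> list[str]:
        return list(self.presence.columns)

    @classmethod
    def from_variant_table(
        cls, table: VariantTable, min_alt: int = 4, min_vaf: float = 0.3
    ) -> "GenotypeMatrix":
        df = table.df[~table.df["sample"].isin(_normal_samples(table))].copy()
        df["key"] = _site_key(df)
        df["alt_total"] = df["alt_fwd"] + df["alt_rev"]
        alt = df.pivot_table(index="sample", columns="key", values="alt_total", aggfunc="sum", fill_value=0)
        depth = df.pivot_table(index="sample", columns="key", values="depth", aggfunc="sum", fill_value=0)
        fwd = df.pivot_table(index="sample", columns="key", values="alt_fwd", aggfunc="sum", fill_value=0)
        rev = df.pivot_table(index="sample", columns="key", values="alt_rev", aggfunc="sum", fill_value=0)
        vaf = alt / depth.replace(0, np.nan)
        presence = (alt >= min_alt) & (vaf.fillna(0) >= min_vaf) & (fwd >= 1) & (rev >= 1)
        return cls(presence=presence.sort_index(), alt=alt.sort_index(), depth=depth.sort_index())


# ---------------------------------------------------------------------------
# Mutation trees
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    name: str
    parent: str | None
    children: list[str] = field(default_factory=list)
    raw_length: float = 0.0
    scaled_length: float = 0.0
    mutations: list = field(default_factory=list)


@dataclass
class MutationTree:
    """Rooted tree over clonal units with per-branch mutation counts.

    The root represents the matched-normal (zero somatic mutation) ancestor;
    every other node's incoming branch may carry mutations.  ``scaled_length``
    is ``raw_length / (1 - excluded_fraction)``.
    """

    nodes: dict[str, TreeNode]
    root: str
    parsimony_score: int | None = None
    excluded_fraction: float = 0.0

    def leaves(self) -> list[str]:
        return sorted(n.name for n in self.nodes.values() if not n.children)

    def clade(self, name: str) -> frozenset:
        out, stack = [], [name]
        while stack:
            n = self.nodes[stack.pop()]
            if not n.children:
                out.append(n.name)
            stack.extend(n.children)
        return frozenset(out)

    def branches(self) -> list[str]:
        """Non-root nodes in deterministic root-down order."""
        order: list[str] = []
        stack = [self.root]
        while stack:
            n = self.nodes[stack.pop()]
            if n.name != self.root:
                order.append(n.name)
            stack.extend(sorted(n.children, reverse=True))
        return order

    def depth(self, name: str) -> int:
        d, node = 0, name
        while self.nodes[node].parent is not None:
            node = self.nodes[node].parent
            d += 1
        return d

    def path_length(self, leaf: str, scaled: bool = True) -> float:
        total, node = 0.0, leaf
        while node != self.root:
            n = self.nodes[node]
            total += n.scaled_length if scaled else n.raw_length
            node = n.parent
        return total

    def copy(self) -> "MutationTree":
        nodes = {
            k: TreeNode(v.name, v.parent, list(v.children), v.raw_length, v.scaled_length, list(v.mutations))
            for k, v in self.nodes.items()
        }
        return MutationTree(nodes, self.root, self.parsimony_score, self.excluded_fraction)

    def newick(self, scaled: bool = True) -> str:
        def render(name: str) -> str:
            node = self.nodes[name]
            length = node.scaled_length if scaled else node.raw_length
            if not node.children:
                return f"{name}:{length:g}"
            inner = ",".join(render(c) for c in sorted(node.children))
            label = "" if name == self.root else name
            return f"({inner}){label}:{length:g}" if name != self.root else f"({inner}){name}"

        return render(self.root) + ";"


# ---------------------------------------------------------------------------
# Maximum parsimony
# ---------------------------------------------------------------------------


def _enumerate_rooted_shapes(leaves: list[int]):
    """All rooted binary tree shapes over ``leaves`` (nested pairs), generated
    by inserting each successive leaf on every branch.  (2n-3)!! shapes."""

    def insertions(tree, leaf):
        yield (tree, leaf)
        if isinstance(tree, tuple):
            l, r = tree
            for t in insertions(l, leaf):
                yield (t, r)
            for t in insertions(r, leaf):
                yield (l, t)

    def rec(i, tree):
        if i == len(leaves):
            yield tree
            return
        for t in insertions(tree, leaves[i]):
            yield from rec(i + 1, t)

    if len(leaves) == 1:
        yield leaves[0]
    else:
        yield from rec(1, leaves[0])


def _fitch_score(tree, has0: list[int], has1: list[int], charmask: int, weights) -> int:
    """Weighted Fitch small-parsimony score of a shape, with character state
    sets packed as bitmasks over characters (two ints per node)."""

    def rec(node):
        if not isinstance(node, tuple):
            return has0[node], has1[node], 0
        l0, l1, ls = rec(node[0])
        r0, r1, rs = rec(node[1])
        i0, i1 = l0 & r0, l1 & r1
        empty = charmask & ~(i0 | i1)
        if weights is None:
            sc = empty.bit_count()
        else:
            sc, e = 0, empty
            while e:
                b = e & -e
                sc += weights[b.bit_length() - 1]
                e ^= b
        h0 = i0 | (empty & (l0 | r0))
        h1 = i1 | (empty & (l1 | r1))
        return h0, h1, ls + rs + sc

    return rec(tree)[2]


def _nni_neighbours(tree):
    """All trees one nearest-neighbour interchange away (deterministic order)."""
    out = []

    def rec(node, rebuild):
        if not isinstance(node, tuple):
            return
        l, r = node
        if isinstance(l, tuple):
            ll, lr = l
            out.append(rebuild(((ll, r), lr)))
            out.append(rebuild(((lr, r), ll)))
        if isinstance(r, tuple):
            rl, rr = r
            out.append(rebuild((rr, (rl, l))))
            out.append(rebuild((rl, (rr, l))))
        rec(l, lambda t: rebuild((t, r)))
        rec(r, lambda t: rebuild((l, t)))

    rec(tree, lambda t: t)
    return out


def _shape_to_tree(shape, taxa: list[str], outgroup_index: int, score: int) -> MutationTree:
    """Root a shape (which contains the outgroup leaf) at the outgroup."""
    # Build adjacency.
    adj: dict[object, list] = {}
    counter = [0]

    def walk(node):
        if not isinstance(node, tuple):
            return node
        counter[0] += 1
        me = f"__i{counter[0]}"
        for child in node:
            c = walk(child)
            adj.setdefault(me, []).append(c)
            adj.setdefault(c, []).append(me)
        return me

    top = walk(shape)
    # The shape is rooted arbitrarily; treat it as unrooted (its top node has
    # degree 2 and is suppressed by rerooting through it).
    nodes: dict[str, TreeNode] = {}

    def leaf_min(x) -> str:
        return min(_collect_leaves(x))

    def _collect_leaves(x) -> list[str]:
        if not (isinstance(x, str) and x.startswith("__i")):
            return [taxa[x]]
        seen, stack, out = {x}, [x], []
        while stack:
            cur = stack.pop()
            for nb in adj[cur]:
                if nb in seen:
                    continue
                seen.add(nb)
                if isinstance(nb, str) and nb.startswith("__i"):
                    stack.append(nb)
                else:
                    out.append(taxa[nb])
        return out

    name_counter = [0]

    def build(node, parent_key, parent_name) -> str:
        internal = isinstance(node, str) and node.startswith("__i")
        if internal:
            kids = [nb for nb in adj[node] if nb != parent_key]
            if len(kids) == 1:  # degree-2 artefact of the arbitrary shape root
                return build(kids[0], node, parent_name)
            name_counter[0] += 1
            name = f"node{name_counter[0]:02d}"
            nodes[name] = TreeNode(name, parent_name)
            if parent_name is not None:
                nodes[parent_name].children.append(name)
            for kid in sorted(kids, key=lambda x: min(_collect_leaves_excl(x, node))):
                build(kid, node, name)
            return name
        name = taxa[node]
        nodes[name] = TreeNode(name, parent_name)
        if parent_name is not None:
            nodes[parent_name].children.append(name)
        return name

    def _collect_leaves_excl(x, parent) -> list[str]:
        if not (isinstance(x, str) and x.startswith("__i")):
            return [taxa[x]]
        seen, stack, out = {x, parent}, [x], []
        while stack:
            cur = stack.pop()
            for nb in adj[cur]:
                if nb in seen:
                    continue
                seen.add(nb)
                if isinstance(nb, str) and nb.startswith("__i"):
                    stack.append(nb)
                else:
                    out.append(taxa[nb])
        return out

    # Root at the outgroup's neighbour; the outgroup leaf becomes the root.
    root_name = "root"
    nodes[root_name] = TreeNode(root_name, None)
    og_neighbour = adj[outgroup_index][0]
    build(og_neighbour, outgroup_index, root_name)
    return MutationTree(nodes=nodes, root=root_name, parsimony_score=score)


def _pack_characters(presence: pd.DataFrame) -> tuple[list[str], list[int], list[int], int, list[int]]:
    """Collapse duplicate characters and pack presence into per-taxon bitmasks."""
    units = sorted(presence.index)
    mat = presence.loc[units].to_numpy(dtype=bool)
    cols, weights = {}, []
    patterns = []
    for j in range(mat.shape[1]):
        pat = mat[:, j].tobytes()
        if pat in cols:
            weights[cols[pat]] += 1
        else:
            cols[pat] = len(weights)
            weights.append(1)
            patterns.append(mat[:, j])
    n_chars = len(weights)
    charmask = (1 << n_chars) - 1
    has1 = []
    for i in range(len(units)):
        bits = 0
        for c in range(n_chars):
            if patterns[c][i]:
                bits |= 1 << c
        has1.append(bits)
    has0 = [charmask & ~b for b in has1]
    return units, has0, has1, charmask, weights


def _greedy_laminar_shape(presence: pd.DataFrame, units: list[str]) -> tuple:
    """Initial shape from mutually compatible (laminar) characters."""
    n = len(units)
    sets: dict[frozenset, int] = {}
    mat = presence.loc[units].to_numpy(dtype=bool)
    for j in range(mat.shape[1]):
        s = frozenset(np.flatnonzero(mat[:, j]).tolist())
        if 0 < len(s) < n:
            sets[s] = sets.get(s, 0) + 1
    accepted: list[frozenset] = []
    for s in sorted(sets, key=lambda s: (-sets[s], -len(s), sorted(s))):
        if all(s <= t or t <= s or not (s & t) for t in accepted):
            accepted.append(s)
    universe = frozenset(range(n))
    family = sorted({universe, *accepted, *(frozenset([i]) for i in range(n))}, key=lambda s: (-len(s), sorted(s)))

    def children_of(s: frozenset) -> list[frozenset]:
        inside = [t for t in family if t < s]
        return [t for t in inside if not any(t < u for u in inside)]

    def build(s: frozenset):
        if len(s) == 1:
            return next(iter(s))
        kids = [build(t) for t in sorted(children_of(s), key=lambda t: min(t))]
        shape = kids[0]
        for k in kids[1:]:
            shape = (shape, k)
        return shape

    return build(universe)


def build_parsimony_tree(
    matrix: GenotypeMatrix | pd.DataFrame,
    max_exhaustive: int = 8,
    outgroup: str = OUTGROUP,
) -> MutationTree:
    """Maximum-parsimony tree over clonal units, rooted by a zero-mutation outgroup.

    Characters are the binary presence patterns of each mutation.  For up to
    ``max_exhaustive`` units the search enumerates every unrooted topology
    (including the outgroup) and scores it with weighted Fitch, so the
    returned parsimony score is the global minimum; ties break
    deterministically on enumeration order (lexicographic leaf insertion).
    Larger instances start from a greedy perfect-phylogeny of the compatible
    characters and hill-climb with nearest-neighbour interchanges.
    """
    presence = matrix.presence if isinstance(matrix, GenotypeMatrix) else matrix
    if len(presence.index) < 2:
        raise ValueError("need at least two clonal units")
    units, has0, has1, charmask, weights = _pack_characters(presence)
    taxa = units + [outgroup]
    og = len(units)
    has1 = has1 + [0]
    has0 = has0 + [charmask]
    w = None if all(x == 1 for x in weights) else weights

    if len(units) <= max_exhaustive:
        best_shape, best_score = None, None
        for rooted in _enumerate_rooted_shapes(list(range(len(units)))):
            shape = (rooted, og)
            score = _fitch_score(shape, has0, has1, charmask, w)
            if best_score is None or score < best_score:
                best_shape, best_score = shape, score
    else:
        shape = (_greedy_laminar_shape(presence, units), og)
        best_shape = shape
        best_score = _fitch_score(shape, has0, has1, charmask, w)
        improved = True
        while improved:
            improved = False
            for cand in _nni_neighbours(best_shape):
                score = _fitch_score(cand, has0, has1, charmask, w)
                if score < best_score:
                    best_shape, best_score = cand, score
                    improved = True
                    break
    return _shape_to_tree(best_shape, taxa, og, int(best_score))


def parsimony_placement(tree: MutationTree, presence: pd.DataFrame) -> dict[str, str | None]:
    """Branch carrying each mutation under perfect-phylogeny placement.

    For a compatible character the most parsimonious placement is the branch
    whose clade equals the character's presence set; incompatible characters
    map to None.
    """
    clade_to_branch = {tree.clade(b): b for b in tree.branches()}
    out = {}
    for mut in presence.columns:
        s = frozenset(presence.index[presence[mut]])
        out[mut] = clade_to_branch.get(s)
    return out


# ---------------------------------------------------------------------------
# Maximum-likelihood mutation assignment and branch scaling
# ---------------------------------------------------------------------------


def assign_mutations_ml(
    tree: MutationTree,
    matrix: GenotypeMatrix,
    purity: float | dict[str, float] = 1.0,
    epsilon: float = 1e-4,
) -> MutationTree:
    """Assign each mutation to the branch maximising a binomial likelihood.

    For branch ``b`` the expected VAF is 0.5 x purity in samples descending
    from ``b`` (heterozygous diploid) and ``epsilon`` elsewhere; the mutation
    goes to the argmax branch (ties resolved towards the root, then by
    name).  Mutations with zero mutant reads everywhere are flagged
    unassignable and excluded from branch lengths.
    """
    leaves = tree.leaves()
    if set(leaves) - set(matrix.units):
        raise ValueError("tree leaves missing from genotype matrix")
    if isinstance(purity, dict):
        pur = np.array([purity[s] for s in leaves])
    else:
        pur = np.full(len(leaves), float(purity))
    if (pur <= 0).any() or (pur > 1).any():
        raise ValueError("purity must be in (0, 1]")

    alt = matrix.alt.loc[leaves].to_numpy().T  # M x S
    depth = matrix.depth.loc[leaves].to_numpy().T
    eps = max(epsilon, 1e-12)
    p_in = np.clip(0.5 * pur, eps, 1.0)[None, :]
    ll_in = stats.binom.logpmf(alt, depth, p_in)
    ll_out = stats.binom.logpmf(alt, depth, eps)
    delta = ll_in - ll_out  # M x S

    branches = sorted(tree.branches(), key=lambda b: (tree.depth(b), b))
    leaf_index = {s: i for i, s in enumerate(leaves)}
    mask = np.zeros((len(branches), len(leaves)))
    for bi, b in enumerate(branches):
        for s in tree.clade(b):
            mask[bi, leaf_index[s]] = 1.0
    scores = delta @ mask.T  # M x B (common ll_out term omitted: constant per mutation)
    assigned = np.asarray(scores).argmax(axis=1)
    assignable = alt.sum(axis=1) > 0

    out = tree.copy()
    for node in out.nodes.values():
        node.mutations = []
        node.raw_length = 0.0
    muts = matrix.mutations
    for m, (bi, ok) in enumerate(zip(assigned, assignable)):
        if not ok:
            continue
        node = out.nodes[branches[bi]]
        node.mutations.append(muts[m])
        node.raw_length += 1
    f = out.excluded_fraction
    for node in out.nodes.values():
        node.scaled_length = node.raw_length / (1 - f)
    return out


def scale_branches(tree: MutationTree, excluded_fraction: float) -> MutationTree:
    """Scale branch lengths for the genome fraction excluded by CN filtering.

    Every branch's scaled length is raw / (1 - excluded_fraction); the
    topology and raw lengths are untouched, so scaling conserves all branch
    ratios.
    """
    if not 0 <= excluded_fraction < 1:
        raise ValueError("excluded fraction must be in [0, 1)")
    out = tree.copy()
    out.excluded_fraction = excluded_fraction
    for node in out.nodes.values():
        node.scaled_length = node.raw_length / (1 - excluded_fraction)
    return out
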