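"""Clonal-architecture simulator.

Generates rooted tumour phylogenies under two evolutionary modes and emits
the synthetic sequencing observations the rest of the package consumes:

* **comb** -- a short trunk of mutations shared by every tumour cell,
  followed by many near-independent private branches.  This is the
  normal-tissue-like architecture of hypomutated infant tumours: the most
  recent common ancestor arises in early gestation, so almost the whole
  per-cell burden is private to small clones and invisible to bulk
  sequencing.
* **sweep** -- a long trunk with a few large nested subclones, the classical
  picture of iterative driver acquisition and clonal sweeps seen in more
  highly mutated tumours and adult cancers.

Observation layers: whole-genome bulk read counts at configurable depth
(default 30X), single-molecule duplex read bundles with a configurable
per-read error rate, genotype matrices for ~100-cell microbiopsies treated
as clonal units, matched-normal observations including low-allele-fraction
embryonic mosaic variants, and per-sample copy-number segment tables.

Every operation is deterministic given its seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genome as genome_model
from .bulk_burden import VariantTable
from .duplex_burden import ConsensusParams, DEFAULT_PARAMS, DuplexBundleSet
from .genome import BASES, DIPLOID_GENOME_SIZE, GENOME_LENGTH, offsets_to_loci

__all__ = [
    "SimulationConfig",
    "ClonalPhylogeny",
    "BiopsyGenotypes",
    "BulkNoiseModel",
    "DuplexNoiseModel",
    "simulate_phylogeny",
    "preset_library",
    "sample_biopsies",
    "simulate_bulk_reads",
    "simulate_duplex_bundles",
    "simulate_copy_number",
    "add_matched_normal",
    "write_fixtures",
    "PRESET_NAMES",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """All simulator knobs, with presets calibrated in :func:`preset_library`."""

    architecture_mode: str = "comb"  # "comb" | "sweep"
    trunk_range: tuple[int, int] = (9, 26)  # inclusive range of trunk length
    n_clones: int = 20
    private_mean: float = 300.0  # negative-binomial mean of private branch length
    private_dispersion: float = 10.0
    clone_concentration: float = 5.0  # Dirichlet concentration of comb clone fractions
    subclone_fractions: tuple[float, ...] = (0.5, 0.3, 0.2)  # sweep mode
    subclone_branch_mean: float = 20.0
    purity: float = 1.0  # tumour-cell fraction of the bulk sample
    bulk_depth: int = 30
    duplex_interrogated_bases: int = 1_000_000_000
    duplex_error_rate: float = 1e-3
    reads_per_strand: int = 2
    n_biopsies: int = 25
    cells_per_biopsy: int = 100
    biopsy_admixture: float = 0.05  # minor sibling-clone fraction per biopsy
    n_germline_sites: int = 100
    n_embryonic_mosaic: int = 2
    mosaic_fraction_range: tuple[float, float] = (0.02, 0.10)
    seed: int = 0

    def validate(self) -> None:
        if self.architecture_mode not in ("comb", "sweep"):
            raise ValueError(f"unknown architecture mode {self.architecture_mode!r}")
        lo, hi = self.trunk_range
        if lo > hi or lo < 0:
            raise ValueError("empty trunk range")
        if self.n_clones < 1:
            raise ValueError("need at least one clone")
        if self.private_mean < 0 or self.private_dispersion <= 0:
            raise ValueError("invalid private branch distribution")
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")
        if self.bulk_depth < 1:
            raise ValueError("bulk depth must be >= 1")
        if not 0 <= self.duplex_error_rate < 0.1:
            raise ValueError("duplex error rate must be in [0, 0.1)")
        if self.architecture_mode == "sweep":
            f = np.asarray(self.subclone_fractions, float)
            if len(f) < 1 or (f <= 0).any() or abs(f.sum() - 1) > 1e-6:
                raise ValueError("sweep subclone fractions must be positive and sum to 1")


PRESET_NAMES = (
    "neonatal_comb",
    "schoolage_sweep",
    "colorectal_sweep",
    "neonatal_normal_kidney",
    "schoolage_normal_kidney",
)

# Per-cell burden anchors (mutations per diploid genome): neonatal normal
# kidney 65-92, school-age normal kidney 221-248.  Preset calibration solves
# trunk + expected subclonal path + private mean = target midpoint.
_NEONATAL_TARGET = (65 + 92) / 2  # 78.5
_SCHOOLAGE_TARGET = (221 + 248) / 2  # 234.5


def _sweep_path_mean(fractions: tuple[float, ...], branch_mean: float) -> float:
    # Expected subclonal (non-trunk, non-private) path length in the nested
    # caterpillar: clone i sits below i-1 subclone branches.
    return sum(f * i * branch_mean for i, f in enumerate(fractions))


def preset_library(name: str) -> SimulationConfig:
    """Named simulator configurations anchored to the study conditions.

    ``neonatal_*`` presets target per-cell burdens near 65--92 and
    ``schoolage_*`` near 221--248 mutations per diploid genome;
    ``colorectal_sweep`` emulates an adult colorectal cancer with a trunk of
    thousands of mutations.  Tumour presets sample 25 microbiopsies of 100
    cells (20--30 biopsies of ~100 cells in the study design).
    """
    if name == "neonatal_comb":
        trunk = (9, 26)
        return SimulationConfig(
            architecture_mode="comb",
            trunk_range=trunk,
            n_clones=20,
            private_mean=_NEONATAL_TARGET - (trunk[0] + trunk[1]) / 2,
        )
    if name == "schoolage_sweep":
        trunk = (170, 190)
        sub = (0.5, 0.3, 0.2)
        branch_mean = 20.0
        return SimulationConfig(
            architecture_mode="sweep",
            trunk_range=trunk,
            n_clones=len(sub),
            subclone_fractions=sub,
            subclone_branch_mean=branch_mean,
            private_mean=_SCHOOLAGE_TARGET - (trunk[0] + trunk[1]) / 2 - _sweep_path_mean(sub, branch_mean),
        )
    if name == "colorectal_sweep":
        return SimulationConfig(
            architecture_mode="sweep",
            trunk_range=(2400, 2600),
            n_clones=3,
            subclone_fractions=(0.5, 0.3, 0.2),
            subclone_branch_mean=100.0,
            private_mean=300.0,
        )
    if name == "neonatal_normal_kidney":
        return SimulationConfig(
            architecture_mode="comb",
            trunk_range=(0, 0),
            n_clones=50,
            private_mean=_NEONATAL_TARGET,
        )
    if name == "schoolage_normal_kidney":
        return SimulationConfig(
            architecture_mode="comb",
            trunk_range=(0, 0),
            n_clones=50,
            private_mean=_SCHOOLAGE_TARGET,
        )
    raise KeyError(f"unknown preset {name!r}; choose one of {PRESET_NAMES}")


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


@dataclass
class SimNode:
    name: str
    parent: str | None
    children: list[str] = field(default_factory=list)
    mutations: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))


@dataclass
class ClonalPhylogeny:
    """Ground-truth rooted mutation-bearing tree of tumour lineages.

    ``leaves`` maps clone name to its fraction of *tumour* cells (summing to
    1); ``normal_contamination_fraction`` is the admixed non-tumour cell
    fraction of the bulk sample.  ``catalog`` holds one row per mutation
    (chrom, pos, ref, alt, branch, origin).
    """

    nodes: dict[str, SimNode]
    leaves: dict[str, float]
    architecture_mode: str
    trunk_mutation_count: int
    normal_contamination_fraction: float
    catalog: pd.DataFrame
    config: SimulationConfig
    root: str = "root"

    def __post_init__(self) -> None:
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root")
        if abs(sum(self.leaves.values()) - 1) > 1e-9:
            raise ValueError("clone fractions must sum to 1")

    def path_mutations(self, leaf: str) -> np.ndarray:
        ids, node = [], leaf
        while node is not None:
            ids.append(self.nodes[node].mutations)
            node = self.nodes[node].parent
        return np.concatenate(ids[::-1]) if ids else np.empty(0, np.int64)

    def clone_burden(self, leaf: str) -> int:
        return int(self.path_mutations(leaf).size)

    def mean_per_cell_burden(self) -> float:
        """Clone-fraction-weighted mean root-to-leaf mutation count."""
        return float(sum(frac * self.clone_burden(leaf) for leaf, frac in self.leaves.items()))

    def subtree_leaves(self, node: str) -> list[str]:
        out, stack = [], [node]
        while stack:
            n = stack.pop()
            if n in self.leaves:
                out.append(n)
            stack.extend(self.nodes[n].children)
        return out

    def mutation_cell_fractions(self) -> pd.Series:
        """Fraction of tumour cells carrying each somatic mutation."""
        frac_by_branch = {
            name: sum(self.leaves[l] for l in self.subtree_leaves(name)) for name in self.nodes
        }
        out = np.zeros(len(self.catalog))
        for name, node in self.nodes.items():
            out[node.mutations] = frac_by_branch[name]
        return pd.Series(np.clip(out, 0.0, 1.0), index=self.catalog.index)

    def shared_prefix_count(self) -> int:
        """Number of mutations on the shared prefix of all root-to-leaf paths."""
        node = self.root
        count = len(self.nodes[node].mutations)
        while len(self.nodes[node].children) == 1:
            node = self.nodes[node].children[0]
            count += len(self.nodes[node].mutations)
        return count

    def bulk_genotypes(self, name: str = "bulk") -> "BiopsyGenotypes":
        """The whole tumour as a single mixed sample (per-mutation cell fractions)."""
        fractions = pd.DataFrame([self.mutation_cell_fractions()], index=[name])
        return BiopsyGenotypes(fractions=fractions, dominant_clone={name: "*"}, tree=self,
                               sample_class={name: "tissue"})

    def to_newick(self) -> str:
        def render(name: str) -> str:
            node = self.nodes[name]
            length = len(node.mutations)
            if not node.children:
                return f"{name}:{length}"
            inner = ",".join(render(c) for c in sorted(node.children))
            return f"({inner}){name}:{length}"

        return render(self.root) + ";"


def _negbin(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size).astype(np.int64)


def _place_mutations(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Uniform placement over the genome model under infinite sites."""
    offsets = rng.integers(0, GENOME_LENGTH, size=n)
    while len(np.unique(offsets)) < n:  # vanishing probability at studied burdens
        dup = pd.Series(offsets).duplicated().to_numpy()
        offsets[dup] = rng.integers(0, GENOME_LENGTH, size=int(dup.sum()))
    chrom, pos = offsets_to_loci(offsets)
    ref = rng.integers(0, 4, size=n)
    alt = (ref + rng.integers(1, 4, size=n)) % 4
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "ref": [BASES[b] for b in ref],
            "alt": [BASES[b] for b in alt],
            "origin": "somatic",
        }
    )


def simulate_phylogeny(config: SimulationConfig) -> ClonalPhylogeny:
    """Draw a clonal phylogeny under the configured architecture mode."""
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    lo, hi = config.trunk_range
    trunk_len = int(rng.integers(lo, hi + 1))

    branch_lengths: dict[str, int] = {}
    nodes: dict[str, SimNode] = {"root": SimNode("root", None)}
    leaves: dict[str, float] = {}

    def add(name: str, parent: str, n_mut: int) -> None:
        nodes[name] = SimNode(name, parent)
        nodes[parent].children.append(name)
        branch_lengths[name] = int(n_mut)

    k = config.n_clones
    clone_names = [f"clone{i:02d}" for i in range(k)]
    if k == 1:
        private = int(_negbin(rng, config.private_mean, config.private_dispersion, 1)[0])
        add(clone_names[0], "root", trunk_len + private)
        leaves[clone_names[0]] = 1.0
    elif config.architecture_mode == "comb":
        add("mrca", "root", trunk_len)
        privates = _negbin(rng, config.private_mean, config.private_dispersion, k)
        fractions = rng.dirichlet(np.full(k, config.clone_concentration))
        for name, n_mut, frac in zip(clone_names, privates, fractions):
            add(name, "mrca", int(n_mut))
            leaves[name] = float(frac)
    else:  # sweep: nested caterpillar of large subclones
        fractions = np.asarray(config.subclone_fractions, float)
        fractions = fractions / fractions.sum()
        privates = _negbin(rng, config.private_mean, config.private_dispersion, k)
        subs = _negbin(rng, config.subclone_branch_mean, config.private_dispersion, k)
        add("mrca", "root", trunk_len)
        # Clone i sits below i subclone branches: clone 0 hangs off the MRCA,
        # each later clone below one further nested subclone branch; the last
        # clone's private branch absorbs its own subclone branch.
        parent = "mrca"
        for i, name in enumerate(clone_names):
            if i < k - 1:
                add(name, parent, int(privates[i]))
                if i < k - 2:
                    nxt = f"sub{i + 1:02d}"
                    add(nxt, parent, int(subs[i + 1]))
                    parent = nxt
            else:
                add(name, parent, int(subs[i]) + int(privates[i]))
            leaves[name] = float(fractions[i])

    # Assign mutation identifiers breadth-first so the trunk gets the lowest ids.
    total = sum(branch_lengths.values())
    catalog = _place_mutations(rng, total)
    catalog["branch"] = ""
    next_id = 0
    order = ["root"]
    queue = list(nodes["root"].children)
    while queue:
        name = queue.pop(0)
        order.append(name)
        queue.extend(nodes[name].children)
    for name in order:
        if name == "root":
            continue
        n_mut = branch_lengths[name]
        ids = np.arange(next_id, next_id + n_mut, dtype=np.int64)
        nodes[name].mutations = ids
        catalog.loc[ids, "branch"] = name
        next_id += n_mut

    tree = ClonalPhylogeny(
        nodes=nodes,
        leaves=leaves,
        architecture_mode=config.architecture_mode,
        trunk_mutation_count=trunk_len if k > 1 else total,
        normal_contamination_fraction=1 - config.purity,
        catalog=catalog,
        config=config,
    )
    assert tree.shared_prefix_count() == tree.trunk_mutation_count
    return tree


# ---------------------------------------------------------------------------
# Microbiopsy sampling
# ---------------------------------------------------------------------------


@dataclass
class BiopsyGenotypes:
    """Per-sample mutant-cell fractions (samples x mutations)."""

    fractions: pd.DataFrame
    dominant_clone: dict[str, str]
    tree: ClonalPhylogeny
    sample_class: dict[str, str] = field(default_factory=dict)
    catalog: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.sample_class:
            self.sample_class = {s: "tissue" for s in self.fractions.index}

    def get_catalog(self) -> pd.DataFrame:
        return self.catalog if self.catalog is not None else self.tree.catalog

    @property
    def samples(self) -> list[str]:
        return list(self.fractions.index)


def sample_biopsies(
    tree: ClonalPhylogeny,
    n_biopsies: int,
    cells_per_biopsy: int,
    seed: int,
    admixture: float | None = None,
) -> BiopsyGenotypes:
    """Draw microbiopsies, each dominated by one locally-expanded clone.

    Laser-capture microbiopsies of ~100 cells are small, spatially separated
    and largely clonal; each is modelled as ``cells_per_biopsy`` cells of one
    dominant clone with a binomial admixture (default 5%) from a random
    sibling clone, making the clonal-unit approximation testable rather than
    hard-coded.  Matrix entries are the fraction of biopsy cells carrying
    each mutation, so trunk mutations are always at fraction 1.
    """
    if not tree.leaves:
        raise ValueError("empty tree")
    if n_biopsies < 1 or cells_per_biopsy < 1:
        raise ValueError("need at least one biopsy of at least one cell")
    if admixture is None:
        admixture = tree.config.biopsy_admixture
    rng = np.random.default_rng([seed, 2])
    clones = sorted(tree.leaves)
    probs = np.array([tree.leaves[c] for c in clones])
    probs = probs / probs.sum()
    dominant_idx = rng.choice(len(clones), size=n_biopsies, p=probs)

    carrier_sets = {c: set(tree.path_mutations(c).tolist()) for c in clones}
    n_mut = len(tree.catalog)
    rows, dominant = [], {}
    for b, di in enumerate(dominant_idx):
        name = f"biopsy_{b:02d}"
        dom = clones[di]
        dominant[name] = dom
        parent = tree.nodes[dom].parent
        siblings = [c for c in tree.nodes[parent].children if c != dom and c in tree.leaves]
        n_adm = 0
        sib = None
        if admixture > 0 and siblings:
            sib = siblings[int(rng.integers(len(siblings)))]
            n_adm = int(rng.binomial(cells_per_biopsy, admixture))
        frac = np.zeros(n_mut)
        dom_ids = np.fromiter(carrier_sets[dom], dtype=np.int64, count=len(carrier_sets[dom]))
        frac[dom_ids] += (cells_per_biopsy - n_adm) / cells_per_biopsy
        if n_adm and sib is not None:
            sib_ids = np.fromiter(carrier_sets[sib], dtype=np.int64, count=len(carrier_sets[sib]))
            frac[sib_ids] += n_adm / cells_per_biopsy
        rows.append(frac)
    fractions = pd.DataFrame(rows, index=list(dominant), columns=tree.catalog.index)
    return BiopsyGenotypes(fractions=fractions, dominant_clone=dominant, tree=tree)


def add_matched_normal(
    genotypes: BiopsyGenotypes,
    seed: int,
    n_germline: int | None = None,
    n_mosaic: int | None = None,
    mosaic_fraction_range: tuple[float, float] | None = None,
    normal_name: str = "normal",
) -> BiopsyGenotypes:
    """Append a matched-normal sample, germline SNPs and embryonic mosaics.

    Germline variants are heterozygous in every cell of every sample.
    Embryonic mosaic variants are clonal in the tumour (they predate the
    tumour's most recent common ancestor) but sit at a low cell fraction in
    the matched normal -- the class of variant the germline filter must *not*
    remove.
    """
    cfg = genotypes.tree.config
    if n_germline is None:
        n_germline = cfg.n_germline_sites
    if n_mosaic is None:
        n_mosaic = cfg.n_embryonic_mosaic
    if mosaic_fraction_range is None:
        mosaic_fraction_range = cfg.mosaic_fraction_range
    rng = np.random.default_rng([seed, 3])
    catalog = genotypes.get_catalog().copy()
    n_som = len(catalog)
    extra = _place_mutations(rng, n_germline + n_mosaic)
    extra.index = np.arange(n_som, n_som + len(extra))
    extra.loc[extra.index[:n_germline], "origin"] = "germline"
    extra.loc[extra.index[n_germline:], "origin"] = "mosaic"
    extra["branch"] = ""
    catalog = pd.concat([catalog, extra])

    mosaic_frac = rng.uniform(*mosaic_fraction_range, size=n_mosaic)
    # Germline and mosaic sites are clonal in every tumour sample.
    extra_cols = pd.DataFrame(
        1.0, index=genotypes.fractions.index, columns=extra.index
    )
    fractions = pd.concat([genotypes.fractions, extra_cols], axis=1)
    normal_row = np.zeros(len(catalog))
    normal_row[n_som : n_som + n_germline] = 1.0
    normal_row[n_som + n_germline :] = mosaic_frac
    fractions.loc[normal_name] = normal_row
    sample_class = dict(genotypes.sample_class)
    sample_class[normal_name] = "normal"
    return BiopsyGenotypes(
        fractions=fractions,
        dominant_clone={**genotypes.dominant_clone, normal_name: "-"},
        tree=genotypes.tree,
        sample_class=sample_class,
        catalog=catalog,
    )


# ---------------------------------------------------------------------------
# Bulk read simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BulkNoiseModel:
    """Clean/noisy mixture for per-record QC annotations and background error."""

    noisy_fraction: float = 0.02  # records drawn from the mis-mapping mixture
    clean_alignment_range: tuple[int, int] = (140, 161)
    noisy_alignment_range: tuple[int, int] = (60, 140)
    clean_clip_max: float = 0.45
    noisy_clip_range: tuple[float, float] = (0.5, 1.0)
    base_error_rate: float = 1e-4  # per-read chance of a spurious mutant call
    strand_bias: float = 0.5  # forward-strand probability of a mutant read


def simulate_bulk_reads(
    genotypes: BiopsyGenotypes,
    depth: float,
    purity: float,
    seed: int,
    noise: BulkNoiseModel | None = None,
    calling_mode: str = "matched",
) -> VariantTable:
    """Simulate per-sample strand-resolved read counts at every catalogued site.

    Per site and sample the total depth is Poisson around ``depth`` and the
    mutant read count is binomial with success probability
    purity x mutant-cell-fraction x 0.5 (heterozygous diploid), plus a small
    background error rate.  Mutant reads split between strands symmetrically
    unless a strand bias is injected.  Germline and mosaic variants are
    present in non-tumour cells too, so their detection probability does not
    scale with purity.
    """
    if noise is None:
        noise = BulkNoiseModel()
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0 <= purity <= 1:
        raise ValueError("purity must be in [0, 1]")
    F = genotypes.fractions.to_numpy(dtype=float)
    if (F < 0).any() or (F > 1).any():
        raise ValueError("genotype fractions outside [0, 1]")
    catalog = genotypes.get_catalog()
    samples = list(genotypes.fractions.index)
    origins = catalog["origin"].to_numpy()
    purity_factor = np.where(origins == "somatic", purity, 1.0)
    # Normal-class samples contain no tumour cells: their rows already carry
    # the correct fractions (0 for somatic sites).
    p = 0.5 * F * purity_factor[None, :]
    p = np.clip(p + noise.base_error_rate, 0.0, 1.0)

    rng = np.random.default_rng([seed, 4])
    S, M = F.shape
    depth_m = rng.poisson(depth, size=(S, M))
    alt = rng.binomial(depth_m, p)
    fwd = rng.binomial(alt, noise.strand_bias)
    noisy = rng.random((S, M)) < noise.noisy_fraction
    mas = np.where(
        noisy,
        rng.integers(*noise.noisy_alignment_range, size=(S, M)),
        rng.integers(*noise.clean_alignment_range, size=(S, M)),
    )
    clip = np.where(
        noisy,
        rng.uniform(*noise.noisy_clip_range, size=(S, M)),
        rng.uniform(0.0, noise.clean_clip_max, size=(S, M)),
    )

    frames = []
    for i, sample in enumerate(samples):
        frames.append(
            pd.DataFrame(
                {
                    "chrom": catalog["chrom"].to_numpy(),
                    "pos": catalog["pos"].to_numpy(),
                    "ref": catalog["ref"].to_numpy(),
                    "alt": catalog["alt"].to_numpy(),
                    "sample": sample,
                    "depth": depth_m[i],
                    "alt_fwd": fwd[i],
                    "alt_rev": alt[i] - fwd[i],
                    "median_alignment_score": mas[i],
                    "clipped_fraction": clip[i],
                    "true_fraction": F[i],
                    "origin": origins,
                    "true_branch": catalog["branch"].to_numpy(),
                    "mut_id": catalog.index.to_numpy(),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    return VariantTable(df=df, sample_class=dict(genotypes.sample_class), calling_mode=calling_mode)


# ---------------------------------------------------------------------------
# Duplex bundle simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DuplexNoiseModel:
    """Metadata distributions for duplex reads.

    Defaults describe a clean library: the low-quality / low-margin /
    mismatch knobs exist so every downstream consensus filter can be made to
    fire in tests, and are zero or near-zero by default so that the burden
    estimator is unbiased under the default study conditions.
    """

    base_quality: int = 30
    low_quality: int = 2
    low_quality_fraction: float = 0.0
    read_span: int = 75  # positions from a read end a call can occupy
    mismatch_probs: tuple[float, ...] = (0.90, 0.08, 0.015, 0.005)
    margin_high: int = 60
    margin_low: int = 30
    low_margin_fraction: float = 0.03

    def metadata_pass_probability(self, params: ConsensusParams, reads_per_strand: int) -> float:
        """Exact marginal probability that a bundle-base passes the
        variant-independent gates (read-end trim, margin, mismatch load)."""
        n_reads = 2 * reads_per_strand
        p_end = max(0.0, (self.read_span - params.end_trim) / self.read_span)
        p_margin = (1 - self.low_margin_fraction) if self.margin_high > params.min_alignment_margin else 0.0
        p_mm = sum(
            p for k, p in enumerate(self.mismatch_probs) if k <= params.max_mismatches_per_read
        )
        return p_end * p_margin**n_reads * p_mm**n_reads


def _draw_metadata(
    rng: np.random.Generator, noise: DuplexNoiseModel, n: int, r: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    shape = (n, 2, r)
    quals = np.where(
        rng.random(shape) < noise.low_quality_fraction, noise.low_quality, noise.base_quality
    ).astype(np.int16)
    probs = np.asarray(noise.mismatch_probs, dtype=float)
    cum = np.cumsum(probs / probs.sum())
    mism = np.searchsorted(cum, rng.random(shape), side="right").astype(np.int16)
    margins = np.where(
        rng.random(shape) < noise.low_margin_fraction, noise.margin_low, noise.margin_high
    ).astype(np.int16)
    offsets = rng.integers(0, noise.read_span, size=n).astype(np.int16)
    return quals, mism, margins, offsets


def simulate_duplex_bundles(
    tree: ClonalPhylogeny,
    interrogated_bases: int,
    error_rate: float,
    seed: int,
    reads_per_strand: int = 2,
    noise: DuplexNoiseModel | None = None,
    purity: float | None = None,
    non_tumour_burden: float = 0.0,
    params: ConsensusParams = DEFAULT_PARAMS,
    with_coordinates: bool = False,
) -> DuplexBundleSet:
    """Simulate duplex bundle-bases from the cell mixture of a tumour sample.

    Each bundle-base originates from one cell drawn by clone fraction (and
    purity); it covers a site mutated in that cell with probability
    burden / diploid genome size, in which case all reads of both strands
    carry the variant.  Sequencing errors are injected per read
    independently.  Bases where every read equals the reference are kept as
    aggregate counts (see :class:`~clonarch.duplex_burden.DuplexBundleSet`).
    """
    if interrogated_bases < 1:
        raise ValueError("need at least one interrogated base")
    if not 0 <= error_rate < 0.1:
        raise ValueError("error rate must be in [0, 0.1)")
    if noise is None:
        noise = DuplexNoiseModel()
    if purity is None:
        purity = 1 - tree.normal_contamination_fraction
    rng = np.random.default_rng([seed, 5])
    r = reads_per_strand
    n_reads = 2 * r

    clones = sorted(tree.leaves)
    burdens = np.array([tree.clone_burden(c) for c in clones], dtype=float)
    probs = np.array([tree.leaves[c] for c in clones]) * purity
    path_ids = {c: tree.path_mutations(c) for c in clones}
    if purity < 1:
        clones = clones + ["__non_tumour__"]
        burdens = np.append(burdens, non_tumour_burden)
        probs = np.append(probs, 1 - purity)
    probs = probs / probs.sum()
    true_mixture_burden = float((probs * burdens).sum())

    cell_counts = rng.multinomial(int(interrogated_bases), probs)
    n_true_per_clone = rng.binomial(cell_counts, np.minimum(burdens / DIPLOID_GENOME_SIZE, 1.0))
    n_true = int(n_true_per_clone.sum())
    n_bg = int(interrogated_bases) - n_true
    p_err_any = 1 - (1 - error_rate) ** n_reads
    n_bg_err = int(rng.binomial(n_bg, p_err_any)) if error_rate > 0 else 0
    n_bg_clean = n_bg - n_bg_err
    p_meta = noise.metadata_pass_probability(params, r)
    n_bg_interrogated = int(rng.binomial(n_bg_clean, p_meta))

    n_x = n_true + n_bg_err
    ref = rng.integers(0, 4, size=n_x).astype(np.uint8)
    true_alt = ref.copy()
    if n_true:
        true_alt[:n_true] = (ref[:n_true] + rng.integers(1, 4, size=n_true)) % 4
    bases = np.broadcast_to(ref[:, None, None], (n_x, 2, r)).copy()
    bases[:n_true] = np.broadcast_to(true_alt[:n_true, None, None], (n_true, 2, r))

    # Sites (optional; costs memory at large base counts): true-variant
    # bundles take the coordinates of a mutation carried by the originating
    # clone; background ones get uniform positions.
    chrom = pos = None
    if with_coordinates:
        mut_ids = np.empty(n_true, dtype=np.int64)
        start = 0
        for c, k in zip(clones, n_true_per_clone):
            if k == 0:
                continue
            ids = path_ids.get(c)
            if ids is not None and ids.size:
                mut_ids[start : start + k] = rng.choice(ids, size=k)
            else:
                mut_ids[start : start + k] = -1
            start += k
        offsets_bg = rng.integers(0, GENOME_LENGTH, size=n_x - n_true)
        chrom_bg, pos_bg = offsets_to_loci(offsets_bg)
        chrom = np.empty(n_x, dtype=object)
        pos = np.empty(n_x, dtype=np.int64)
        known = mut_ids >= 0 if n_true else np.zeros(0, bool)
        if n_true:
            cat = tree.catalog
            chrom[:n_true] = np.where(known, cat["chrom"].to_numpy()[np.maximum(mut_ids, 0)], "1")
            pos[:n_true] = np.where(known, cat["pos"].to_numpy()[np.maximum(mut_ids, 0)], 1)
            base_codes = np.array([BASES.index(b) for b in cat["ref"]], dtype=np.uint8)
            alt_codes = np.array([BASES.index(b) for b in cat["alt"]], dtype=np.uint8)
            ref[:n_true] = np.where(known, base_codes[np.maximum(mut_ids, 0)], ref[:n_true])
            true_alt[:n_true] = np.where(known, alt_codes[np.maximum(mut_ids, 0)], true_alt[:n_true])
            bases[:n_true] = np.broadcast_to(true_alt[:n_true, None, None], (n_true, 2, r))
        chrom[n_true:] = chrom_bg
        pos[n_true:] = pos_bg

    # Per-read sequencing errors.
    if error_rate > 0:
        err = np.zeros((n_x, n_reads), dtype=bool)
        if n_true:
            err[:n_true] = rng.random((n_true, n_reads)) < error_rate
        if n_bg_err:
            # Conditioned on >= 1 error among the bundle's reads: draw the
            # error count from the truncated binomial, then a uniformly
            # random read subset of that size from a precomputed table.
            kk = np.arange(1, n_reads + 1)
            pmf = np.array(
                [
                    math.comb(n_reads, k) * error_rate**k * (1 - error_rate) ** (n_reads - k)
                    for k in kk
                ]
            )
            cum = np.cumsum(pmf / pmf.sum())
            n_err_reads = 1 + np.searchsorted(cum, rng.random(n_bg_err), side="right")
            subsets = []  # subsets[k] = boolean masks of all k-subsets of reads
            import itertools as _it

            for k in range(n_reads + 1):
                rowset = []
                for combo in _it.combinations(range(n_reads), k):
                    m = np.zeros(n_reads, bool)
                    m[list(combo)] = True
                    rowset.append(m)
                subsets.append(np.array(rowset))
            block = err[n_true:]
            for k in range(1, n_reads + 1):
                sel = n_err_reads == k
                if not sel.any():
                    continue
                choice = rng.integers(len(subsets[k]), size=int(sel.sum()))
                block[sel] = subsets[k][choice]
            err[n_true:] = block
        err = err.reshape(n_x, 2, r)
        shift = rng.integers(1, 4, size=(n_x, 2, r)).astype(np.uint8)
        bases = np.where(err, (bases + shift) % 4, bases).astype(np.uint8)
    bases = bases.astype(np.uint8)

    quals, mism, margins, end_offset = _draw_metadata(rng, noise, n_x, r)
    is_true = np.zeros(n_x, dtype=bool)
    is_true[:n_true] = True
    return DuplexBundleSet(
        ref=ref,
        bases=bases,
        quals=quals,
        mismatches=mism,
        margins=margins,
        end_offset=end_offset,
        is_true_variant=is_true,
        true_alt=true_alt,
        n_background_clean=n_bg_clean,
        n_background_interrogated=n_bg_interrogated,
        reads_per_strand=r,
        error_rate=error_rate,
        true_mixture_burden=true_mixture_burden,
        chrom=chrom,
        pos=pos,
    )


# ---------------------------------------------------------------------------
# Copy number
# ---------------------------------------------------------------------------


def simulate_copy_number(
    samples: list[str],
    seed: int = 0,
    overlays: list[tuple[str, str, int, int, int]] | None = None,
    baseline_cn: int = 2,
):
    """Per-sample genome segmentation, diploid by default.

    ``overlays`` is a list of (sample, chrom, start, end, total_cn) segments
    (0-based half-open) written on top of the flat baseline -- the mechanism
    for injecting copy-number discordance between samples.
    """
    from .phylogeny import CopyNumberProfile

    rows = []
    overlays = overlays or []
    for sample in samples:
        mine = [o for o in overlays if o[0] == sample]
        for chrom, length in genome_model.AUTOSOMES:
            cuts = sorted({0, length} | {o[2] for o in mine if o[1] == chrom} | {o[3] for o in mine if o[1] == chrom})
            for a, b in zip(cuts[:-1], cuts[1:]):
                cn = baseline_cn
                for _, oc, os_, oe, ocn in mine:
                    if oc == chrom and os_ <= a and b <= oe:
                        cn = ocn
                rows.append((sample, chrom, a, b, cn))
    df = pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "total_cn"])
    return CopyNumberProfile(df=df)


# ---------------------------------------------------------------------------
# Fixture serialisation
# ---------------------------------------------------------------------------


def write_fixtures(
    directory: str | Path,
    tree: ClonalPhylogeny | None = None,
    variants: VariantTable | None = None,
    biopsies: BiopsyGenotypes | None = None,
    bundles: DuplexBundleSet | None = None,
    cn_profile=None,
) -> dict[str, Path]:
    """Serialise synthetic observations plus the generating ground truth.

    VCF positions are 1-based; BED intervals 0-based half-open; trees go to
    Newick with branch lengths in mutations; ground truth to JSON.
    """
    from . import cli_io

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if tree is not None:
        p = directory / "tree.nwk"
        p.write_text(tree.to_newick() + "\n")
        paths["tree"] = p
        truth = {
            "architecture_mode": tree.architecture_mode,
            "trunk_mutation_count": int(tree.trunk_mutation_count),
            "mean_per_cell_burden": tree.mean_per_cell_burden(),
            "clone_fractions": {k: float(v) for k, v in sorted(tree.leaves.items())},
            "normal_contamination_fraction": tree.normal_contamination_fraction,
            "n_mutations": int(len(tree.catalog)),
            "config": dataclasses.asdict(tree.config),
        }
        p = directory / "truth.json"
        p.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
        paths["truth"] = p
    if variants is not None:
        p = directory / "variants.vcf"
        cli_io.write_vcf(variants, p)
        paths["vcf"] = p
    if biopsies is not None:
        p = directory / "biopsy_genotypes.tsv"
        biopsies.fractions.rename_axis("sample").to_csv(p, sep="\t")
        paths["genotypes"] = p
    if bundles is not None:
        p = directory / "duplex_bundles.tsv"
        bundles.to_frame().to_csv(p, sep="\t", index=False)
        paths["bundles"] = p
        p = directory / "duplex_background.json"
        p.write_text(
            json.dumps(
                {
                    "n_background_clean": bundles.n_background_clean,
                    "n_background_interrogated": bundles.n_background_interrogated,
                    "reads_per_strand": bundles.reads_per_strand,
                    "error_rate": bundles.error_rate,
                },
                indent=2,
            )
            + "\n"
        )
        paths["bundle_background"] = p
    if cn_profile is not None:
        p = directory / "copy_number.bed"
        cli_io.write_bed(cn_profile, p)
        paths["bed"] = p
    return paths
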