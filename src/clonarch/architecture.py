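"""Tree-shape and burden-discrepancy statistics.

These statistics operationalise the central claim the package exists to
reproduce: when a tumour's phylogeny is comb-like (a trunk of only tens of
mutations followed by long private branches), bulk sequencing -- which only
sees mutations shared by a large fraction of cells -- reports a small
fraction of the true per-cell burden, while single-molecule duplex
sequencing recovers it.  Under a sweep-like architecture the two estimates
agree.  The fold change (duplex / bulk) and the absolute difference are the
headline comparison; the detected fraction (bulk / per-cell) drives a simple
configurable architecture classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .duplex_burden import BurdenEstimate
from .phylogeny import MutationTree

__all__ = [
    "ArchitectureReport",
    "trunk_length",
    "per_cell_burden",
    "burden_discrepancy",
    "classify_architecture",
    "total_distinct_mutations",
    "TotalMutationEstimate",
    "build_report",
]


def trunk_length(tree: MutationTree, scaled: bool = True) -> float:
    """Scaled mutation count on the path from the root to the first split.

    The trunk is the branch set from the root down to the first node with at
    least two tumour descendants -- the mutations shared by every sampled
    tumour cell.
    """
    if tree.root not in tree.nodes:
        raise ValueError("tree has no root")
    total = 0.0
    node = tree.root
    while True:
        children = tree.nodes[node].children
        if len(children) != 1:
            break
        node = children[0]
        n = tree.nodes[node]
        total += n.scaled_length if scaled else n.raw_length
    return total


def per_cell_burden(tree: MutationTree, scaled: bool = True) -> float:
    """Mean over leaves of the total root-to-leaf mutation count."""
    leaves = tree.leaves()
    if not leaves:
        raise ValueError("empty tree")
    return float(np.mean([tree.path_length(l, scaled=scaled) for l in leaves]))


def burden_discrepancy(
    bulk: BurdenEstimate, duplex: BurdenEstimate
) -> tuple[float | None, float]:
    """(duplex/bulk fold change, duplex - bulk absolute difference).

    The fold change is None when the bulk burden is zero (undefined); the
    absolute difference is always reported.
    """
    b = bulk.mutations_per_diploid_genome
    d = duplex.mutations_per_diploid_genome
    fold = None if b == 0 else d / b
    return fold, d - b


def classify_architecture(
    detected_fraction: float,
    comb_threshold: float = 0.5,
    sweep_threshold: float = 0.8,
) -> str:
    """Classify an architecture from the detected fraction (bulk / per-cell).

    Below ``comb_threshold`` the bulk assay missed most of the per-cell
    burden (comb-like, polyclonal); above ``sweep_threshold`` it captured
    almost all of it (sweep-like); in between is reported as intermediate.
    The thresholds are an operationalisation, not a literature constant, and
    the classification is invariant to uniform rescaling of all burdens.
    """
    if detected_fraction < comb_threshold:
        return "comb"
    if detected_fraction > sweep_threshold:
        return "sweep"
    return "intermediate"


@dataclass(frozen=True)
class TotalMutationEstimate:
    value: float
    order_of_magnitude: tuple[float, float]  # [10^k, 10^(k+1)) band containing value


def total_distinct_mutations(
    tree: MutationTree,
    n_cells: float,
    per_cell_private: float,
    mean_clone_size: float,
) -> TotalMutationEstimate:
    """Order-of-magnitude count of distinct mutations across all tumour cells.

    Distinct mutations are counted per clonal lineage (not per cell, to
    avoid double counting mutations shared within a clone):
    trunk + (n_cells / mean_clone_size) x private mutations per lineage.
    At realistic tumour sizes (millions of cells each carrying >100 private
    mutations) this lands in the hundreds of millions.
    """
    if n_cells < 1:
        raise ValueError("need at least one cell")
    if mean_clone_size <= 0:
        raise ValueError("clone size must be positive")
    trunk = trunk_length(tree)
    value = trunk + (n_cells / mean_clone_size) * per_cell_private
    k = math.floor(math.log10(value)) if value > 0 else 0
    return TotalMutationEstimate(value=value, order_of_magnitude=(10.0**k, 10.0 ** (k + 1)))


@dataclass
class ArchitectureReport:
    """Summary statistics comparing bulk and single-molecule burden views."""

    trunk_length: float
    per_cell_burden: float
    bulk_burden: float
    duplex_burden: float
    fold_change: float | None
    absolute_difference: float
    detected_fraction: float
    architecture_class: str
    total_distinct_mutations: float | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def build_report(
    tree: MutationTree | None,
    bulk: BurdenEstimate,
    duplex: BurdenEstimate,
    comb_threshold: float = 0.5,
    sweep_threshold: float = 0.8,
    n_cells: float | None = None,
    mean_clone_size: float = 1.0,
) -> ArchitectureReport:
    """Assemble the architecture report from a tree and the two burden estimates.

    The detected fraction uses the reconstructed tree's per-cell burden when
    a tree is available, otherwise the duplex estimate stands in for it.
    """
    trunk = trunk_length(tree) if tree is not None else 0.0
    pcb = per_cell_burden(tree) if tree is not None else duplex.mutations_per_diploid_genome
    fold, diff = burden_discrepancy(bulk, duplex)
    reference = pcb if pcb > 0 else duplex.mutations_per_diploid_genome
    detected = bulk.mutations_per_diploid_genome / reference if reference > 0 else 1.0
    total = None
    if n_cells is not None and tree is not None:
        total = total_distinct_mutations(
            tree, n_cells, per_cell_private=max(pcb - trunk, 0.0), mean_clone_size=mean_clone_size
        ).value
    return ArchitectureReport(
        trunk_length=trunk,
        per_cell_burden=pcb,
        bulk_burden=bulk.mutations_per_diploid_genome,
        duplex_burden=duplex.mutations_per_diploid_genome,
        fold_change=fold,
        absolute_difference=diff,
        detected_fraction=detected,
        architecture_class=classify_architecture(detected, comb_threshold, sweep_threshold),
        total_distinct_mutations=total,
    )
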