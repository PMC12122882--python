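"""Single-molecule (duplex) consensus calling and burden estimation.

A duplex *read bundle* is the set of reads derived from one original DNA
molecule, grouped by source strand.  Because a true substitution is present
on both strands of the molecule while most sequencing and library artefacts
are single-stranded, requiring an identical non-reference consensus from the
two strands suppresses the error rate to roughly the square of the per-read
error rate.  This module implements the bundle-level consensus rules, the
accounting of interrogated bundle-bases, and the conversion of the resulting
call rate into mutations per diploid genome with a Poisson (Garwood)
uncertainty interval.

Calling rules (a substitution is accepted only if all hold):

* at least two reads from each of the two original strands,
* every supporting read has an alignment-score margin (best minus
  second-best alignment score) greater than 50,
* every supporting read carries at most two mismatches,
* the call is at least 8 bp from the nearer read end,
* each strand's reads agree on the base, both strand consensuses agree,
  the shared base differs from the reference, and the consensus base
  quality (the minimum quality of the strand's reads -- the conservative
  aggregation) is at least 6.

Interrogated-base accounting: a bundle-base counts towards the burden
denominator iff it passes every *variant-independent* gate (bundle
completeness, alignment margin, mismatch load, read-end trim).  This keeps
the denominator consistent with the numerator, as in error-corrected
sequencing practice.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import stats

from .genome import BASES, DIPLOID_GENOME_SIZE

__all__ = [
    "DuplexRead",
    "DuplexBundle",
    "DuplexBundleSet",
    "ConsensusParams",
    "CallOutcome",
    "BurdenEstimate",
    "consensus_call",
    "call_bundles",
    "duplex_burden",
    "contamination_adjusted_burden",
    "garwood_interval",
]

# Rejection reasons, in the order the rules are applied.
REASON_INCOMPLETE = "incomplete_bundle"
REASON_READ_END = "read_end_proximity"
REASON_MISMATCHES = "excess_mismatches"
REASON_MARGIN = "low_alignment_margin"
REASON_QUALITY = "low_consensus_quality"
REASON_DISCORDANT = "strand_discordant"


@dataclass(frozen=True)
class ConsensusParams:
    """Thresholds of the duplex consensus rules."""

    min_reads_per_strand: int = 2
    min_consensus_quality: int = 6
    min_alignment_margin: int = 50  # supporting reads must exceed this
    max_mismatches_per_read: int = 2
    end_trim: int = 8  # calls closer than this to a read end are discarded


DEFAULT_PARAMS = ConsensusParams()


@dataclass(frozen=True)
class DuplexRead:
    base: str
    quality: int
    end_offset: int  # distance in bp to the nearer read end
    mismatches: int
    alignment_margin: int  # best minus second-best alignment score


@dataclass
class DuplexBundle:
    """All reads derived from one original DNA duplex at one site."""

    chrom: str
    pos: int  # 1-based
    ref: str
    strand_reads: tuple[list[DuplexRead], list[DuplexRead]]

    def reads(self) -> list[DuplexRead]:
        return list(self.strand_reads[0]) + list(self.strand_reads[1])


@dataclass(frozen=True)
class CallOutcome:
    status: str  # "variant" | "reference" | "rejected"
    reason: str | None = None
    alt: str | None = None
    interrogated: bool = False


def consensus_call(bundle: DuplexBundle, params: ConsensusParams = DEFAULT_PARAMS) -> CallOutcome:
    """Apply the duplex consensus rules to one bundle.

    Rejection is a return value, never an exception; the ``reason`` records
    the first failing rule in the documented order.  ``interrogated`` is True
    iff the bundle-base passes all variant-independent gates and therefore
    contributes to the burden denominator regardless of the call itself.
    """
    s0, s1 = bundle.strand_reads
    if len(s0) < params.min_reads_per_strand or len(s1) < params.min_reads_per_strand:
        return CallOutcome("rejected", REASON_INCOMPLETE)
    reads = bundle.reads()
    if min(r.end_offset for r in reads) < params.end_trim:
        return CallOutcome("rejected", REASON_READ_END)
    if max(r.mismatches for r in reads) > params.max_mismatches_per_read:
        return CallOutcome("rejected", REASON_MISMATCHES)
    if min(r.alignment_margin for r in reads) <= params.min_alignment_margin:
        return CallOutcome("rejected", REASON_MARGIN)

    # Variant-independent gates passed: the base is interrogated.
    cons = []
    for strand in (s0, s1):
        bases = {r.base for r in strand}
        if len(bases) != 1:
            return CallOutcome("rejected", REASON_DISCORDANT, interrogated=True)
        cons.append((bases.pop(), min(r.quality for r in strand)))
    (b0, q0), (b1, q1) = cons
    if b0 != b1:
        return CallOutcome("rejected", REASON_DISCORDANT, interrogated=True)
    if b0 == bundle.ref:
        return CallOutcome("reference", interrogated=True)
    if min(q0, q1) < params.min_consensus_quality:
        return CallOutcome("rejected", REASON_QUALITY, interrogated=True)
    return CallOutcome("variant", alt=b0, interrogated=True)


# ---------------------------------------------------------------------------
# Vectorised bundle sets (the simulator's output representation)
# ---------------------------------------------------------------------------


@dataclass
class DuplexBundleSet:
    """A collection of duplex bundle-bases in array form.

    Only "interesting" bundle-bases are materialised read-by-read: those
    covering a site mutated in the originating cell, and those where at least
    one read carries a sequencing error.  The (vastly more numerous) bases
    where every read equals the reference are kept as aggregate counts, with
    the number passing the variant-independent metadata gates drawn from the
    same per-read metadata distributions.  This keeps simulation of 1e8-1e10
    bundle-bases tractable without changing any distributional property a
    downstream filter can see.
    """

    ref: np.ndarray  # (n,) uint8 base codes
    bases: np.ndarray  # (n, 2, r) uint8 called bases
    quals: np.ndarray  # (n, 2, r) int16
    mismatches: np.ndarray  # (n, 2, r) int16
    margins: np.ndarray  # (n, 2, r) int16
    end_offset: np.ndarray  # (n,) int16; shared by the bundle's reads
    is_true_variant: np.ndarray  # (n,) bool ground truth
    true_alt: np.ndarray  # (n,) uint8
    n_background_clean: int  # all-reference bundle-bases not materialised
    n_background_interrogated: int  # of those, passing the metadata gates
    reads_per_strand: int = 2
    error_rate: float = 0.0
    true_mixture_burden: float = 0.0  # mean burden of the sampled cell mixture
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None

    @property
    def n_explicit(self) -> int:
        return int(self.ref.shape[0])

    @property
    def n_bundle_bases(self) -> int:
        return self.n_explicit + self.n_background_clean

    def bundle(self, i: int) -> DuplexBundle:
        strands = []
        for s in range(2):
            strands.append(
                [
                    DuplexRead(
                        base=BASES[self.bases[i, s, r]],
                        quality=int(self.quals[i, s, r]),
                        end_offset=int(self.end_offset[i]),
                        mismatches=int(self.mismatches[i, s, r]),
                        alignment_margin=int(self.margins[i, s, r]),
                    )
                    for r in range(self.reads_per_strand)
                ]
            )
        chrom = self.chrom[i] if self.chrom is not None else "1"
        pos = int(self.pos[i]) if self.pos is not None else i + 1
        return DuplexBundle(chrom=str(chrom), pos=pos, ref=BASES[self.ref[i]], strand_reads=(strands[0], strands[1]))

    def iter_bundles(self, limit: int | None = None) -> Iterator[DuplexBundle]:
        n = self.n_explicit if limit is None else min(limit, self.n_explicit)
        for i in range(n):
            yield self.bundle(i)

    def permuted(self, seed: int) -> "DuplexBundleSet":
        """Return a copy with the explicit bundles in shuffled order."""
        order = np.random.default_rng(seed).permutation(self.n_explicit)
        kwargs = {}
        for name in ("ref", "bases", "quals", "mismatches", "margins", "end_offset", "is_true_variant", "true_alt"):
            kwargs[name] = getattr(self, name)[order]
        if self.chrom is not None:
            kwargs["chrom"] = self.chrom[order]
        if self.pos is not None:
            kwargs["pos"] = self.pos[order]
        return replace(self, **kwargs)

    def to_frame(self) -> pd.DataFrame:
        """Explicit bundles as a flat table (one row per bundle-base)."""
        n, r = self.n_explicit, self.reads_per_strand
        cols: dict[str, object] = {
            "chrom": self.chrom if self.chrom is not None else np.repeat("1", n),
            "pos": self.pos if self.pos is not None else np.arange(1, n + 1),
            "ref": [BASES[b] for b in self.ref],
            "end_offset": self.end_offset,
            "is_true_variant": self.is_true_variant,
        }
        for s in range(2):
            for j in range(r):
                tag = f"s{s}r{j}"
                cols[f"base_{tag}"] = [BASES[b] for b in self.bases[:, s, j]]
                cols[f"qual_{tag}"] = self.quals[:, s, j]
                cols[f"mm_{tag}"] = self.mismatches[:, s, j]
                cols[f"margin_{tag}"] = self.margins[:, s, j]
        return pd.DataFrame(cols)


@dataclass
class DuplexCallResult:
    n_interrogated: int
    n_variant: int
    n_reference: int
    rejection_counts: dict[str, int]
    variant_mask: np.ndarray  # over explicit bundles
    true_positive: int
    false_positive: int
    false_negative: int


def call_bundles(bundles: DuplexBundleSet, params: ConsensusParams = DEFAULT_PARAMS) -> DuplexCallResult:
    """Vectorised consensus calling over a :class:`DuplexBundleSet`.

    Behaviourally identical to mapping :func:`consensus_call` over every
    explicit bundle (asserted by the test suite), plus the aggregate
    accounting of the non-materialised all-reference bundle-bases.
    """
    r = bundles.reads_per_strand
    if r < params.min_reads_per_strand:
        # Every bundle incomplete; nothing interrogated.
        n = bundles.n_explicit
        return DuplexCallResult(0, 0, 0, {REASON_INCOMPLETE: n}, np.zeros(n, bool), 0, 0, int(bundles.is_true_variant.sum()))

    flat = lambda a: a.reshape(a.shape[0], a.shape[1] * a.shape[2])  # noqa: E731
    ok_end = bundles.end_offset >= params.end_trim
    ok_mm = (flat(bundles.mismatches) <= params.max_mismatches_per_read).all(axis=1)
    ok_margin = (flat(bundles.margins) > params.min_alignment_margin).all(axis=1)
    interrogated = ok_end & ok_mm & ok_margin

    strand_same = (bundles.bases == bundles.bases[:, :, :1]).all(axis=2)  # (n,2)
    cons_base = bundles.bases[:, :, 0]
    cons_qual = bundles.quals.min(axis=2)
    concordant = strand_same.all(axis=1) & (cons_base[:, 0] == cons_base[:, 1])
    is_ref = concordant & (cons_base[:, 0] == bundles.ref)
    qual_ok = cons_qual.min(axis=1) >= params.min_consensus_quality
    variant = interrogated & concordant & ~is_ref & qual_ok

    reference = interrogated & is_ref
    rejected_quality = interrogated & concordant & ~is_ref & ~qual_ok
    rejected_discordant = interrogated & ~concordant

    counts = {
        REASON_READ_END: int((~ok_end).sum()),
        REASON_MISMATCHES: int((ok_end & ~ok_mm).sum()),
        REASON_MARGIN: int((ok_end & ok_mm & ~ok_margin).sum()),
        REASON_QUALITY: int(rejected_quality.sum()),
        REASON_DISCORDANT: int(rejected_discordant.sum()),
    }
    truth = bundles.is_true_variant
    tp = int((variant & truth & (cons_base[:, 0] == bundles.true_alt)).sum())
    fp = int(variant.sum()) - tp
    # False negatives are counted over *interrogated* true-variant bases: a
    # base rejected by the variant-independent gates never entered the
    # denominator, so it is not a consensus failure.
    fn = int((truth & interrogated & ~variant).sum())
    return DuplexCallResult(
        n_interrogated=int(interrogated.sum()) + bundles.n_background_interrogated,
        n_variant=int(variant.sum()),
        n_reference=int(reference.sum()) + bundles.n_background_interrogated,
        rejection_counts=counts,
        variant_mask=variant,
        true_positive=tp,
        false_positive=fp,
        false_negative=fn,
    )


# ---------------------------------------------------------------------------
# Burden estimation
# ---------------------------------------------------------------------------


@dataclass
class BurdenEstimate:
    """Mutations per diploid genome, with a 95% uncertainty interval."""

    mutations_per_diploid_genome: float
    method: str  # "bulk" | "duplex"
    n_calls: int
    ci95: tuple[float, float]
    interrogated_bases: float | None = None
    effective_coverage: float | None = None
    adjusted_for_contamination: bool = False
    sample: str | None = None

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        v = self.mutations_per_diploid_genome
        if not (lo - 1e-9 <= v <= hi + 1e-9):
            raise ValueError("interval must contain the point estimate")
        if v < 0:
            raise ValueError("burden must be non-negative")

    @property
    def value(self) -> float:
        return self.mutations_per_diploid_genome


def garwood_interval(k: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Garwood) confidence interval for a Poisson count ``k``."""
    lo = 0.0 if k == 0 else 0.5 * stats.chi2.ppf(alpha / 2, 2 * k)
    hi = 0.5 * stats.chi2.ppf(1 - alpha / 2, 2 * k + 2)
    return float(lo), float(hi)


def duplex_burden(
    bundles: DuplexBundleSet | DuplexCallResult,
    diploid_genome_size: float = DIPLOID_GENOME_SIZE,
    params: ConsensusParams = DEFAULT_PARAMS,
    sample: str | None = None,
) -> BurdenEstimate:
    """Estimate mutations per diploid genome from duplex bundles.

    burden = (variant calls / interrogated bundle-bases) * diploid genome
    size, with the Poisson interval on the call count propagated through the
    same scaling.
    """
    result = bundles if isinstance(bundles, DuplexCallResult) else call_bundles(bundles, params)
    if result.n_interrogated <= 0:
        raise ValueError("no interrogated bundle-bases")
    scale = diploid_genome_size / result.n_interrogated
    k = result.n_variant
    lo, hi = garwood_interval(k)
    return BurdenEstimate(
        mutations_per_diploid_genome=k * scale,
        method="duplex",
        n_calls=k,
        ci95=(lo * scale, hi * scale),
        interrogated_bases=float(result.n_interrogated),
        sample=sample,
    )


def contamination_adjusted_burden(
    estimate: BurdenEstimate, non_tumour_fraction: float, non_tumour_burden: float
) -> BurdenEstimate:
    """Correct an observed burden for admixed non-tumour cells.

    The observed burden is a mixture (1-f)*tumour + f*non-tumour; inverting
    gives tumour burden = (observed - f * non_tumour_burden) / (1 - f).
    Infiltrating immune/stromal cells typically carry fewer mutations than
    tumour cells, so the unadjusted estimate is biased downwards.
    """
    f = non_tumour_fraction
    if not 0 <= f < 1:
        raise ValueError("non_tumour_fraction must be in [0, 1)")
    adj = lambda x: max(0.0, (x - f * non_tumour_burden) / (1 - f))  # noqa: E731
    lo, hi = estimate.ci95
    return replace(
        estimate,
        mutations_per_diploid_genome=adj(estimate.mutations_per_diploid_genome),
        ci95=(adj(lo), adj(hi)),
        adjusted_for_contamination=True,
    )
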