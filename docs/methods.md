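# Methods

## The problem

Bulk whole-genome sequencing of a tumour observes each genomic site as a
pool of reads from millions of cells. A substitution is only called when a
substantial fraction of those cells carry it, so the bulk "mutation burden"
is really the count of mutations shared by large cell populations. Duplex
(single-molecule, NanoSeq-style) sequencing instead calls mutations present
on individual DNA molecules, and therefore measures the *per-cell* burden
regardless of how the mutations are shared.

Whether these two numbers agree is a property of the tumour's clonal
architecture. If evolution proceeded through clonal sweeps, most of the
per-cell burden is truncal and bulk sequencing captures it. If instead the
tumour grew from an early embryonic ancestor without further sweeps — a
normal-tissue-like, "comb" architecture with a trunk of only tens of
mutations and private branches hundreds of mutations long — bulk sequencing
reports a small fraction of the per-cell burden and the tumour looks
hypomutated. `clonarch` simulates both architectures with their full
observation layers and implements the inference machinery needed to expose
and quantify the discrepancy.

## Clonal-architecture simulator

A tumour is a rooted phylogeny of clones. In **comb** mode the tree is a
star: a trunk branch whose length is drawn uniformly from a configurable
integer range (default 9–26), then `n_clones` leaves (default 20) with
private branch lengths drawn from a negative binomial (mean and dispersion
configurable; dispersion 10 by default — the private lengths of real
lineages are overdispersed relative to Poisson because lineages differ in
division history). Clone fractions are Dirichlet with concentration 5,
giving realistic unevenness without letting one clone dominate. In
**sweep** mode the tree is a nested caterpillar: a long trunk, then
subclones of configured fractions (default 0.5/0.3/0.2) separated by
negative-binomial subclone branches.

Mutations are placed uniformly over a 22-autosome genome model under an
infinite-sites assumption, which is safe at the burdens studied (tens to
thousands of mutations against 2.9 Gb). Burdens are reported per diploid
genome using the conventional 6.2 Gb constant.

Preset calibration solves `trunk + expected subclonal path + private mean =
target midpoint`, with targets anchored to duplex measurements of normal
kidney: 65–92 mutations per diploid genome for neonates/infants (midpoint
78.5) and 221–248 for school-age children (midpoint 234.5). The
`colorectal_sweep` preset models an adult carcinoma (trunk ~2500). Tumour
presets sample 25 microbiopsies of 100 cells, inside the 20–30 × ~100-cell
design the analysis assumes.

### Observation layers

**Microbiopsies.** Each biopsy is dominated by one clone drawn by clone
fraction, with a binomial 5% admixture from a random sibling clone — the
"clonal unit" assumption is therefore approximately true in the simulation,
not hard-coded, and the pipeline's robustness to mild admixture is testable.
Matrix entries are fractions of biopsy cells carrying each mutation; trunk
mutations are always at fraction 1.

**Bulk reads.** Per site and sample, depth is Poisson around the configured
coverage (default 30X) and mutant reads are binomial with success
probability `purity × cell fraction × 0.5` (heterozygous diploid), plus a
1e-4 background error. Mutant reads split between strands symmetrically
(bias injectable). QC annotations come from a clean/noisy mixture: 2% of
records draw a low median alignment score and a high clipped fraction, so
the alignment-quality filter has something to remove.

**Matched normal.** 100 germline heterozygous sites (present in every
sample at VAF ~0.5) and 2 embryonic mosaic variants (normal cell fraction
uniform on 2–10%, clonal in the tumour) are appended. Mosaics model
early-development mutations that predate the tumour's ancestor — the class
the germline filter must not remove.

**Duplex bundles.** Each bundle-base originates from one cell drawn by
clone fraction and purity; it covers a mutated site with probability
`burden / 6.2e9`, in which case all four reads (two per strand) carry the
variant. Per-read errors are injected independently. Read metadata
(qualities, alignment-score margins, mismatch counts, distance from the
read end) is drawn from configurable distributions whose defaults describe
a clean library; each knob exists to make the corresponding consensus
filter fire in tests. For tractability at 1e8–1e10 bundle-bases, bases
where every read equals the reference are kept as aggregate counts, with
the number passing the variant-independent metadata gates drawn from the
exact marginal of the same distributions; only mutation-covering and
error-bearing bases are materialised read-by-read. This changes no
distribution a downstream filter can observe (asserted by tests comparing
the vectorised caller with the per-bundle one).

## Duplex consensus calling and burden

A substitution is called from a bundle iff: two reads per strand; every
read's alignment-score margin (best minus second-best) exceeds 50; at most
two mismatches per read; the call at least 8 bp from the nearer read end;
both strand consensuses agree on the same non-reference base; and the
consensus quality — the minimum quality of the strand's reads, the
conservative choice where the aggregation is not pinned down — is at least 6.
Rejection reasons are reported in a fixed rule order, but rule order can
only change the recorded reason, never the outcome.

A bundle-base is **interrogated** iff it passes every variant-independent
gate (completeness, margin, mismatch load, end trim). The burden is
`calls / interrogated × 6.2e9`, with a Garwood (exact Poisson) 95% interval
on the call count — counts are in the tens, so normal approximations are
inappropriate. Admixed non-tumour cells dilute the estimate; the
contamination adjustment inverts the mixture,
`(observed − f × non-tumour burden) / (1 − f)`.

Sampling precision: with `N` interrogated bases and true burden `B`, the
expected number of calls is `N × B / 6.2e9` (≈1.3 per 1e8 bases at
neonatal-kidney burdens), and the estimate's relative standard error is
`1/sqrt(calls)`. The test suite contains one recovery check at exactly that
small scale (where the sampling SE is ~15% of the estimate) and one at
error-free high precision (tens of thousands of calls, SE ~0.5%)
demonstrating statistical consistency of the estimator.

## Bulk burden

Post-processing keeps records whose supporting reads have median alignment
score ≥140 and clipped fraction <0.5 (records with no mutant reads pass
vacuously — they encode absence, which multi-sample genotyping needs).
Organoid samples additionally require VAF >0.3, suppressing mutations
acquired in culture. Coverage is harmonised by thinning each sample to a
target mean depth (default 30X): retained depth is binomial in the thinning
ratio, retained mutant reads hypergeometric from the finite read pool.

Because the simulator does not re-implement a probabilistic caller, a
substitution counts as bulk-called when supported by ≥4 mutant reads on
both strands — a transparent, configurable stand-in. The bulk burden is the
(median across samples of the) count of passing records.

## Phylogeny construction

Filters, applied per site across samples:

1. **Germline.** Removed iff the matched normal is consistent with clonal
   heterozygosity (exact binomial against VAF 0.5, not rejected at
   α=0.01) *and* the tumour is not significantly enriched over the normal.
   The enrichment test computes `P(X ≤ normal_alt | normal_depth, pooled
   tumour VAF)` — an exact binomial comparison of the two VAFs evaluated in
   the direction where the null probability is estimated from hundreds of
   pooled tumour reads rather than one 30X normal, which makes the test
   stable at matched-normal depths (α=0.001). Embryonic mosaics fail the
   clonal-heterozygosity condition and survive. Germline filtering runs on
   raw counts, before QC, so a QC-failed normal record cannot blind it.
2. **Strand imbalance.** Two-sided exact binomial on pooled
   forward/reverse mutant counts against p=1/2; removal at α=0.001. Sites
   with a handful of mutant reads are untestable and retained.
3. **Confidence somewhere.** ≥4 mutant reads, VAF ≥0.3, both strands, in
   at least one tumour sample.
4. **Copy-number concordance.** Variants in regions whose total copy
   number differs between samples are removed (`standard` mode); for
   genomes where nearly everything is discordant, only deleted regions are
   excluded (`deletion_only`). The excluded genomic fraction `f` is
   returned, and branch lengths are later scaled by `1/(1−f)` (which
   conserves all branch ratios).

The alphas are deliberately conservative at 30X; all are configuration.

**Tree building.** Binary presence characters (the per-unit confidence
criteria) over clonal units, rooted by a zero-mutation outgroup standing
for the matched normal genome. Up to 8 units the search enumerates every
unrooted topology containing the outgroup and scores it with weighted
Fitch parsimony over bit-packed characters, so the score is the global
minimum; ties break on a fixed enumeration order. Larger instances start
from a greedy perfect-phylogeny built from the mutually compatible
(laminar) characters and hill-climb with nearest-neighbour interchanges —
instances here are 20–30 leaves with mostly compatible characters, for
which this is reliable (and is cross-checked against exhaustive search at
8 leaves and an external exact branch-and-bound solver in the tests).

**Mutation assignment.** Each mutation goes to the branch maximising a
product of per-sample binomial likelihoods with expected VAF `0.5 × purity`
in samples descending from the branch and ε (default 1e-4) elsewhere; ties
resolve towards the root. As ε→0 on noise-free clonal counts this
reproduces perfect-phylogeny placement exactly. Mutations with no mutant
reads anywhere are flagged unassignable and excluded from branch lengths.
Variants in concordant non-diploid regions would need `mutant copies /
total copies` in place of 0.5; the pipeline works in the diploid model and
exposes the expected-VAF factor as a parameter rather than guessing
mutant multiplicities.

## Architecture statistics

The trunk is the scaled mutation count from the root to the first node
with ≥2 tumour descendants; the per-cell burden is the mean root-to-leaf
scaled path length. The headline comparison is the fold change
(duplex/bulk) and absolute difference. The classifier maps the detected
fraction (bulk / per-cell) to comb (<0.5), sweep (>0.8) or intermediate —
thresholds are an operationalisation (the underlying claim is qualitative)
and are configurable; classification is invariant to uniform rescaling of
all burdens. The total-distinct-mutation estimate counts private mutations
per clonal lineage, `trunk + (n_cells / clone size) × private per lineage`,
to avoid double counting within clones; at 1e6+ cells with >100 private
mutations each this lands in the hundreds of millions.

Reconstructed trunks are compared against `simulated trunk + embryonic
mosaic count`: mosaic variants predate the tumour ancestor and are carried
by every tumour cell, so a correct reconstruction places them on the trunk.

## Driver annotation

Rules, each cited by the call it produces: hotspot missense/in-frame in
oncogenes; truncating events in recessive gene footprints; manual rescue of
promoter hotspot sites that standard callers reject (simple repeats);
focal (<1 Mb) homozygous deletions over recessive genes; focal
amplifications over oncogenes above a ploidy-dependent threshold (copy
number >4 diploid, >8 tetraploid), with sub-threshold amplifications
admitted on expression z ≥2; rearrangements forming whitelisted fusions,
disrupting recessive footprints, or juxtaposing an oncogene's regulatory
domain to an active promoter with elevated expression (z ≥2) — the
promoter-swap mechanism that activates FOXR2 in infant tumours. The z
cutoff of 2 (two-sided 5%) is a documented choice where "significantly
high" is otherwise unquantified. A driver is clonal if its mutation
assigns to the trunk. The bundled gene list is synthetic and illustrative
(real censuses are licensed); it exists to exercise every rule.

## Determinism and problem sizes

Every stochastic step takes an explicit seed and uses numpy Generator
streams keyed by (seed, stage); a rerun of the full pipeline with the same
configuration is byte-identical, and no artefact contains wall-clock
values. The test suite and `scripts/acceptance.py` run the method at
deliberately scaled problem sizes — 1e8–2e10 duplex bundle-bases,
10–50 replicates per experiment, 25 biopsies at 30X — chosen so that each
check's sampling error is small relative to the effect it asserts
(the one exception, a recovery check pinned to ~45 total duplex calls, is
documented above with its ~15% sampling SE).

## What the simulation does not capture

Real data differ in ways the generator deliberately omits: mutational
signatures and trinucleotide context (mutations are uniform over the
genome); mapping artefacts with locus structure (QC noise is i.i.d.);
population SNPs (germline sites are simulated directly rather than through
a panel-of-normals mask); indels and structural variants as burden classes;
sequencing-depth autocorrelation along the genome; and selection within
the growing tumour. Passing tests therefore show that the inference
machinery is correct under the stated generative model, not that the model
captures every property of patient sequencing data.
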