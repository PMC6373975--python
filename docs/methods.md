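# Methods

## The inference problem

A transposable element (TE) family found in two species can have reached
them in two ways: vertical inheritance from their common ancestor, or a
horizontal transfer (HT) across the species barrier. Under vertical
inheritance the TE copies have been diverging since the host species split,
so their synonymous divergence (dS) should resemble the genome-wide neutral
divergence of the two hosts. A TE whose dS falls far below that expectation
was transferred. `httscan` implements this argument end to end for a
multi-species amplicon survey: family clustering, a conservative dS outlier
test, minimal-event counting on the host chronogram, and a constrained
permutation null for per-taxon transfer excess, plus a synthetic-data
generator that makes the whole pipeline testable with known ground truth.

## Family clustering

Within each TE superfamily, sequences are clustered by single linkage on
pairwise hits: an edge requires at least 80% nucleotide identity over at
least 80% of the shorter sequence (both thresholds inclusive), and families
are the connected components of that graph. Either orientation of an
asymmetric hit pair may supply the edge. Species represented by fewer than
two specimens are then dropped from each family — demanding two independent
specimens per species is the survey's guard against contamination — and
families left empty disappear. Family ids are assigned deterministically
from the smallest member sequence id, so output does not depend on hit
order.

## Synonymous divergence

dS is estimated with the Nei–Gojobori (1986) counting method: fractional
synonymous sites per codon, observed differences classified by averaging
over all orderings of the changed positions (pathways through stop codons
excluded; mutations *to* stop codons counted as nonsynonymous in site
counting), and a Jukes–Cantor multiple-hit correction
`dS = -(3/4) ln(1 - (4/3) pS)`. The estimate is reported as *undefined* —
not an error — when `pS >= 3/4` (saturation) or when fewer than 10
synonymous sites are comparable; undefined values never count as evidence
for transfer. Codon columns with gaps, ambiguity codes, or stop codons in
either row are skipped. The estimator sits behind a single pluggable
interface so an alternative (e.g. a maximum-likelihood codon model) can be
swapped in without touching callers; ML estimators are deliberately out of
scope.

Before computing dS, near-identical copies from the *same* specimen
(within-specimen PCR/sequencing redundancy) are collapsed by single linkage
at 99% identity on shared columns, keeping the longest member. Copies from
different specimens are never merged, because replication across specimens
is the signal. For each family and species pair, the reported statistic is
the minimum defined dS over all cross-species row pairs.

## Conservative reference matching

The vertical-inheritance null distribution at a host-tree node is an
empirical sample of housekeeping-gene dS values between full-genome
reference species diverging at that node. Distributions exist only at
*eligible* nodes — internal nodes with reference genomes in at least two
child subtrees. For a species pair (a, b) the matched node is the eligible
node of maximal age inside the subtree rooted at MRCA(a, b) (the MRCA
itself included; ties prefer nodes on the a–b path, then the smallest node
id). By construction the matched node is never older than the MRCA, so the
reference underestimates (never overestimates) the pair's expected genomic
dS, and rejecting the null is conservative. Pairs with no eligible node in
scope are *untestable*.

The rejection threshold is the 5% quantile of the matched sample, computed
as the lower empirical order statistic (smallest value with at least 5% of
the sample at or below it, no interpolation — never above an interpolating
convention, hence again conservative). Vertical inheritance is rejected
when TE dS is *strictly* below the threshold; exact equality is vertical.
No multiple-testing correction is applied across the many families that may
test the same species pair — each (family, pair) link is an independent
claim, matching how such surveys report counts.

## Minimal events and scenarios

Species pairs with rejected nulls form, per superfamily, a network of
species sharing horizontally transferred TEs, each edge annotated with its
contributing families. One transfer into the ancestor of a clade explains
every link between that clade and the donor side, so per family the minimal
number of events is counted on the subtree induced by the family's species:
one event per internal node whose child clades are connected by at least
one link. Equivalently (and provably, used as the test oracle), the event
nodes are the distinct MRCAs of the family's links. Counts are summed over
families within a superfamily; two families sharing an event node still
contribute two events.

An event at an internal node does not identify which extant species were
involved. Scenario sampling resolves each event to a concrete pair by
drawing uniformly among the links crossing its node, independently per
event, 1000 times by default; each endpoint species is credited one
transfer. "Transfers per species" is the mean endpoint count over
scenarios, and per-order counts are sums over member species. (Endpoint
counting is the interpretation under which a single order can hold more
event endpoints than the total event count, which the alternative
"distinct species" reading cannot produce; the mean number of distinct
species involved is emitted alongside for comparison.)

## Permutation null for per-taxon excess

Raw per-order counts are incomparable across orders: sample sizes,
superfamily incidence and phylogenetic structure all differ. The null model
relabels the *observed* network: a uniform bijection from its nodes onto a
random equal-size subset of the carrier species (species carrying at least
one family of the superfamily). Degree distribution and topology are
preserved exactly. Draws are rejected while any edge lands on a *forbidden*
pair (one that is untestable in the real data, so could never have been
observed); after 1000 failed draws the model switches to repair mode, where
each forbidden edge is replaced by a uniformly chosen authorized,
previously unconnected node pair (sequentially, connectivity updated after
each replacement) — edge count preserved, topology slightly altered.

Each simulated network is re-analyzed exactly like the observed one.
Because clustered observed networks merge many links into few events,
simulations systematically infer *more* events than observed; per-
simulation per-order endpoint counts are therefore rescaled multiplicatively
so every simulation's event total equals the observed total. The 2.5% and
97.5% quantiles over (by default 1000) simulations form the envelope;
observed counts above the upper quantile flag the order as a transfer
hotspot. A distance profile bins observed and expected event counts by the
MRCA age of the assigned species pair into 25-My windows and reports their
ratio.

One master seed spawns an independent child stream per simulation, so
simulation *i* depends only on child seed *i* regardless of execution order
or thread count. Simulated datasets are re-analyzed with 100 scenario draws
each (vs 1000 on the observed side): per-order means converge quickly and
envelope width is dominated by relabeling variance.

## Synthetic data

The generator produces every pipeline input with the statistical structure
the analysis assumes, plus a truth table.

**Host tree.** Pure-birth (Yule) branching conditioned on the species
count, rescaled to a root age of `tree_age` (default 300 My, an
arthropod-scale radiation). Taxonomic orders are carved by repeatedly
splitting the largest remaining clade until `n_orders` monophyletic groups
partition the tips; sizes are naturally unequal. Reference-genome flags go
to a uniform random subset of tips.

**Reference panels.** Each sample at a node of age *a* emulates one
housekeeping gene: a true per-gene distance drawn from a gamma distribution
with mean `2 * ds_rate * a` (default rate 0.0025 /My) and coefficient of
variation `ds_noise_cv` (default 0.3, per-gene rate variation), then
*estimated* on a finite alignment of `n_codons` synonymous sites (binomial
sampling of the difference proportion, inverted through Jukes–Cantor).
Real reference distributions are collections of finite-alignment estimates;
reproducing their estimation noise is what makes the vertical null hold
exactly for synthetic TE dS values, which carry the same noise. With
`ds_noise_cv=0` the panel degenerates to exact expected values
(deterministic idealized mode). Default panel size 1000 per node.

**TE families.** Each family starts from a random in-frame ancestral
sequence of 150 codons built entirely from fourfold-degenerate codon groups
(Ala/Gly/Pro/Thr/Val/Ser), so every codon contributes exactly one
synonymous site, no stop codon is reachable, and all simulated change is
synonymous. The family occupies the clade below an origin node drawn
uniformly over all tree nodes (tips included); within the clade each
species is present with probability `p_vertical_presence` (default 0.4).
This yields mostly one- and two-species families with occasional sweeping
ones — the size regime real surveys show. Sequences evolve down the host
subtree by Jukes–Cantor substitution at third positions, at rate
`m_f * ds_rate`, where the per-family multiplier `m_f` is gamma with mean
`te_rate_factor` (default 1.15) and the panel's CV. The mean above 1
reflects that TEs are not slowed by the codon-usage selection acting on
housekeeping genes; it makes the dS outlier test conservative, which is the
direction the real design errs in. Each present species yields
`specimens_per_species` (default 2) specimen copies at a within-species
divergence of `intra_species_ds` (default 0.002).

**Planted transfers.** `n_planted_ht` events are distributed round-robin
over superfamilies. For each, a donor is drawn from a random family's
species and a recipient from outside it (both weighted by
`hotspot_multiplier` when they belong to `hotspot_order`); pairs are
redrawn until testable under the reference panel, else recorded as
untestable-by-design. The recipient receives the donor's sequence mutated
to a dS drawn uniformly from [0, 0.2 × the pair's expected genomic dS] —
far below any plausible vertical divergence. The truth table records every
pair with its mechanism, target dS and true event node (the pair's MRCA).

**Hit table.** All-vs-all within superfamily, both orientations, BLAST
outfmt-6 dialect with query/subject lengths appended; pairs below 50%
identity are omitted, as a local-similarity search would. Generated
sequences are ungapped and equal-length, so identity is computed
column-wise; unequal-length inputs fall back to exact global alignment
(match +1, mismatch −1, gap −2).

All randomness flows from one integer seed through named generator streams;
regeneration is byte-identical.

### What the generator does not emulate

No sequencing error, chimeras, PCR bias or read-length variation; no
nonsynonymous evolution, rate heterogeneity across sites, or indels (the
emitted "alignments" are exact); no TE copy-number dynamics within genomes;
no gene flow or incomplete lineage sorting in the host tree. Passing tests
therefore demonstrate the statistical machinery is correct under the
model's own assumptions, not that the pipeline is robust to alignment error
or assembly artifacts in field data.

## Numerical and design choices

- **Quantiles**: rejection thresholds use the lower order statistic (see
  above); envelope quantiles over simulations use NumPy's default linear
  interpolation (they describe a distribution, not a conservative bound).
- **Degenerate inputs**: empty networks simulate to all-zero tables; a
  simulation with zero events takes normalization factor 1; families on a
  single species emit no dS rows; two-tip trees are built directly.
- **Tie-breaks**: equal-age matched nodes prefer on-path nodes then
  smallest id; collapse ties keep the smallest sequence id; family ids sort
  on smallest member.
- **Problem sizes**: the shipped validation suite uses 60-species trees,
  100–200 families per superfamily, 200–1000 null simulations and 100–1000
  scenario draws — sizes at which every stage completes in seconds while
  estimates (calibrated false-positive rates, hotspot envelopes) are stable
  across seeds.

## Known limitations

- The NG86 estimator underestimates dS when transition/transversion bias or
  codon-frequency structure is strong; the cited alternative estimators are
  pluggable but not implemented.
- Each (family, species pair) is tested without multiple-testing
  correction, as in the original design; family-level rate sharing means
  false positives arrive correlated within families.
- The repair step preserves edge counts but not exact topology; on very
  dense networks with many forbidden pairs the simulated ensemble drifts
  from strict degree preservation.
- Event counting is parsimony-style: it brackets the true transfer count
  from below and attributes events to extant species pairs only
  approximately (hence scenario averaging).
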