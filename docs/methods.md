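# Methods

This note records the models, conventions and numerical choices behind
`hetscan`, in the order data flows through the pipeline.

## Distances

Binary (AFLP/RFLP) data use the Nei–Li restriction-fragment distance
`D = 1 − 2·n_xy/(n_x + n_y)` — one minus the Dice-type similarity over
band presences. Shared band *absence* never contributes: absence is not
evidence of homology. A pair of identical all-absent profiles is defined
to have `D = 0`. The `−ln S` transform of the same similarity is available
behind a flag (`nei_li_distance(..., log_transform=True)`) but is not the
default, because the bounded [0, 1] form is what the published
applications of this test family used with neighbour joining.

Genotype (SNP) data use the allele-sharing distance
`D = 1 − (1/2L_obs) Σ_l s_l`, where `s_l` is the multiset intersection of
the two unordered diploid genotypes (AA~AA → 2, AA~AB → 1, AB~AB → 2,
AA~BB → 0, AG~GT → 1). More than two alleles per locus are handled
naturally. A heterozygote shares 2 alleles with itself, so `D(x, x) = 0`.

Missing data are deleted pairwise: each sample pair uses exactly the loci
where both are observed (`L_obs` varies by pair). Listwise deletion would
discard far more information in sparse SNP tables. A pair with no jointly
observed locus is an error in a primary analysis; inside the bootstrap it
aborts only that replicate (see below). Neither distance is guaranteed
metric (triangle inequality is not asserted); symmetry, zero diagonal and
the [0, 1] range are.

Internally, both distances are computed for all pairs at once as matrix
products over indicator planes (band/observation indicators for binary
data; per-allele "≥1 copy" and "≥2 copies" indicators for genotypes, using
`min(a, b) = [a≥1][b≥1] + [a≥2][b≥2]` for counts in {0, 1, 2}), which is
what makes thousands of bootstrap replicates per jackknife series cheap.

## Trees and support

Trees are Saitou–Nei neighbour joining on the Q criterion. Ties in Q are
broken toward the lexicographically smallest active index pair, making the
topology a deterministic function of the matrix. Negative branch lengths
are kept (no clamping); NJ never produces multifurcations, and zero-length
internal edges still count as bipartitions. The merge loop is a numba
kernel; the Python layer reconstructs the tree and its splits from the
merge sequence, and an independent NJ implementation (scikit-bio) is used
as a cross-check oracle in the test suite.

Node identity across trees is the unrooted bipartition, stored canonically
as the side not containing a reference leaf (the smallest leaf label of
the tree at hand). Outgroup rooting affects display and the SC/NA
bookkeeping orientation only, never support values.

Support is bootstrap-across-loci: L loci drawn with replacement, distance,
NJ, repeated B times; a node's support is the percentage of replicates
containing its bipartition. With missing data a resample can leave some
pair with no jointly observed locus; that replicate is discarded and
redrawn (keeping B constant), with a hard stop after 100 consecutive
failures. B < 100 triggers a warning, not an error.

## Taxon jackknife

Default exclusion sets are one per ingroup group; the outgroup is never
excluded. Custom sets and random cross-group individual pairs (never
repeating a pair) can be added. Jackknife matrices are the full matrix
restricted to the remaining rows: loci monomorphic after an exclusion are
retained so all series bootstrap the same locus universe, and because
distances are pairwise, excluding samples cannot change the distances
among the rest. Every series gets its own seed,
`sha256(master_seed, series_name)` truncated below 2^63, so results are
identical whether series run serially or in parallel (joblib), and any
single series can be re-run in isolation.

## Support accounting (SC / NA)

Each internal node of the full tree is mapped into each jackknife column:

1. If the excluded set forms a clade in the full tree and the node is its
   sister, the cell is `SC` (support carryover): removing a taxon
   mechanically inflates its sister's support, hybrid or not, so the cell
   is excluded from all statistics.
2. If the node's restriction to the remaining leaves has fewer than two
   leaves on either side, or coincides with another node's restriction,
   the redundant cell is `NA` ("the node had joined the excluded taxon").
   When restrictions collide, the node unchanged by the exclusion keeps
   the score (or the `SC` mark); among changed nodes the smallest clade
   keeps it. This prevents one jackknife bipartition from being counted in
   two rows.
3. Otherwise the cell is the restricted bipartition's frequency in that
   series' bootstrap trees — 0 if it never occurs, which is what makes
   severe support drops (lower outliers) visible.

Clade orientation for this bookkeeping roots the tree at the outgroup (or
at the smallest non-excluded leaf when there is none). When an excluded
clade's attachment edge collapses, the rooting decides which of the two
merging rows reads `SC` and which `NA`; neither is scored, so outlier
statistics are rooting-independent. A non-monophyletic excluded group has
no sister and produces no `SC` cell; its neighbourhood follows the generic
NA rules.

## Outlier detection

Per node, the sample is the numeric jackknife cells only — the full-tree
column, `SC` and `NA` cells are excluded (the boxplot describes what
taxon removal does, and the full tree is not a removal experiment). Nodes
with fewer than 5 numeric cells are skipped with a warning. Quartiles are
Tukey hinges (medians of half-samples), the convention of the published
boxplot applications of this test; linear-interpolation quantiles are
available via `quartile_method="linear"`. Outliers lie strictly beyond
`hinge ± k·IQR`, `k` = 1.5 by default, 3 for the strict variant; since
fences widen monotonically with k, the k = 3 outlier set is a subset of
the k = 1.5 set by construction. Both directions are reported and
annotated with the causing exclusion; lower outliers are never
auto-interpreted — they typically mark nodes that existed only because of
the hybrid's pull and vanish when it is removed. The `min_two_groups` node
filter (off by default) restricts reporting to nodes joining at least two
groups, the convention most published applications used to suppress
intra-taxon noise.

## Signal classification

Against a simulation truth record, an upper outlier is a *hybrid signal*
iff caused by excluding the hybrid group at a node whose clade contains
descendants of a parent lineage (counted once per indicated lineage, so a
node containing both parents counts twice). A *parent-exclusion signal* is
an upper outlier caused by excluding a parent-lineage taxon at a node that
contained that taxon's samples. Everything else is a false positive,
totalled at both k values and under the ≥2-group filter. A "maximum BS,
but not outlier" signal requires the hybrid-exclusion cell to be the
strict unique maximum of the row while inside the k = 1.5 fence — with
ties (e.g. saturated rows at 100%) nothing is counted, since a shared
maximum carries no information about the excluded taxon. The
false-negative flag is set when no hybrid-exclusion upper outlier occurs
at any parental node at k = 1.5.

## Coalescent simulator

The species tree carries node divergence times τ in expected
substitutions/site (tips at 0, parent strictly older than child) and a
population parameter θ = 4N<sub>e</sub>μ per branch (uniform by default;
the root's θ governs the ancestral population above the root). Within a
branch, k lineages coalesce at rate k(k−1)/θ per unit τ (pairwise rate
2/θ); survivors enter the parent branch, and coalescence continues above
the root until one lineage remains. The expected pairwise divergence of
two haplotypes in one population is therefore exactly θ, which the tests
verify analytically. Mutations are dropped on the gene tree as a Poisson
process with rate 1 per unit branch length; each event replaces the state
by one of the other three nucleotides uniformly (Jukes–Cantor), so
back-mutation can occur.

A SNP locus is a single site on its own gene tree (free recombination
between loci), starting from a uniform ancestral base; loci monomorphic
across the sampled haplotypes are discarded. An AFLP locus is 10
recognition positions on one gene tree; a haplotype carries the band iff
all 10 positions still match the root (ancestral) state, and a diploid
individual scores 1 iff at least one haplotype carries the band
(dominance). Loci with identical band state across all individuals are
discarded. Simulation continues until the requested polymorphic-locus
count is reached; the raw-locus budget defaults to 1000× that count,
sized for the low-θ regime where well under 1% of raw loci are
polymorphic. Each taxon contributes 2 diploid individuals (4 haplotypes)
by default; haplotypes (1,2) and (3,4) form the two individuals.

A hybrid taxon is planted by running two simulations — the hybrid tip
grafted onto parent lineage A at τ_H, then onto parent lineage B at the
same τ_H — for half the loci each, and concatenating the matrices
(odd locus counts round up). Parents therefore contribute equally
(admixture 0.5), and the hybrid's genome is a mosaic of unlinked blocks
inherited from each side. The branch a hybrid grafts onto inherits that
branch's θ.

The built-in `tropheini` preset is a cichlid-tribe-like tree of 18 ingroup
taxa plus an outgroup, 2 diploids per taxon. Its anchors are an ingroup
root at τ = 0.000225 and most-recent splits at τ = 0.00001; the branching
order and the intermediate node times (0.00002–0.00015, outgroup at
0.0003) are this package's own depth-interpolated choice, written out in
`simulate.TROPHEINI_NEWICK`. Four hybridization scenarios are predefined
on it: recent l × s (τ_H = 0.00001 or 0.000002), intermediate
(r,q) × k (0.000025), and ancient (r,q) × (l,m,n) (0.000037); each τ_H
lies inside both parents' terminal branches by construction. A `radiation`
preset places 17 splits evenly over τ = 0.00005–0.000058 for the
near-simultaneous-divergence setting.

What the simulator deliberately omits: recombination within loci,
continuous migration or repeated gene flow (hybrid origin is a single
instantaneous event), mutation models beyond Jukes–Cantor, ascertainment
bias of real SNP arrays, and AFLP scoring noise (size homoplasy,
peak-calling errors). Passing tests therefore show that the engine behaves
correctly under clean coalescent data, not that the test is robust to
those real-data complications.

## Problem sizes and numerical conventions

The test suite and the acceptance script run the simulation study at one
representative scale per condition: 19 taxa × 2 diploids, ~300–4900
polymorphic SNP loci, B = 50–200 bootstrap replicates, 10 replicate seeds
for the planted-hybrid recovery check and a 6-point θ × loci grid for the
false-positive/support relationship. These sizes give stable qualitative
behaviour (majority recovery of the recent hybrid; Spearman ρ ≈ −0.9
between false positives and mean support) with a single-CPU suite.
Support percentages are reported to one decimal; `SC`/`NA` are string
markers distinct from numeric 0. Degenerate inputs are errors, not
silent repairs: fewer than 4 samples, fewer than 3 after an exclusion,
a genotype code outside {0, 1, 2}, non-positive θ or k, τ_H outside the
parent's branch, a raw-locus budget exhausted before the polymorphic
target (the error reports the yield).

## Known limitations

- Neighbour joining only; no likelihood or Bayesian trees, and no
  model-based sequence distances.
- The screen reports signals; it renders no hybrid verdict. False
  positives arise from heterogeneous shared ancestral polymorphism and
  rise steeply as tree support drops; false negatives arise when support
  is saturated, when the hybrid sits sister to a parental lineage (SC
  absorbs the signal), or when its presence rearranges the topology so
  the informative node is absent from the full tree. The alternative-node
  registry and custom-node queries exist precisely to let the analyst
  chase the latter cases by hand.
- Group membership is taken as given; misassigned samples masquerade as
  hybridization signal.
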