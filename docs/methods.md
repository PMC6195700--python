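# Methods

## Model and assumptions

The package tests whether taxonomic groups in a microbial community follow a
competitive-lottery assembly schema. The underlying generative picture is a
two-step model: each sample's total abundance (100%) is first allocated
among groups by some process we do not model (the first step), and each
group's share is then divided among its members by a within-group schema
(the second step). The analysis is concerned only with the second step and
assumes the two steps are independent, that a group follows the same schema
in every sample, and that groups — defined taxonomically, since closely
related taxa are most likely to share a niche and exert priority effects on
one another — are the unit at which assembly rules act. Functional guilds of
unrelated taxa are not detected.

Under the lottery schema one member captures essentially the whole group
niche per sample and the member's identity varies between samples. Two
statistics operationalize this:

* **Winner prevalence** — the fraction of included samples in which some
  member's within-group fraction strictly exceeds the winner cutoff (0.9 by
  default; a cutoff above 0.5 guarantees at most one winner per sample).
* **Winner diversity** — the base-2 Shannon entropy of the winner-identity
  frequencies over winner-bearing samples, normalized by log2 of the number
  of distinct winners, so it ranges over [0, 1].

A sample enters a group's statistics only when the group's summed relative
abundance strictly exceeds 0.5%. This floor is not cosmetic: at a sequencing
depth of 5000 reads, Poisson counting noise at very low abundance routinely
manufactures "winners" out of uniform communities, and the
`poisson_noise_sweep` generator exists to make that visible. At the 0.5%
floor (25 expected reads per member at depth 5000) the artifact prevalence
is indistinguishable from zero.

## Classification

Groups with prevalence > 0.75 and normalized diversity > 0.25 are
*lottery-like*; prevalence > 0.75 with diversity ≤ 0.25 is a *fixed winner*
(one member dominates everywhere — consistent with exclusion but not with a
lottery); anything else is *non-lottery*. All threshold comparisons in the
package are strict inequalities.

Conventions for degenerate cases: with a single distinct winner the
normalization log2(1) = 0 is degenerate and diversity is defined as 0; with
no winners at all diversity is reported as missing (not 0) and the group is
non-lottery.

## Inclusion filters

Processing order is fixed: drop samples with fewer than 5000 reads (on
counts) → convert to relative abundance on the full retained feature set →
drop features not strictly above 0.05% abundance in at least
max(10, ceil(0.5% of samples)) samples → drop groups not strictly above
0.5% abundance by the same sample rule (an absolute override, e.g. "> 200
samples", replaces the rule for very large cohorts). Columns are **not**
renormalized after feature removal, so within-group fractions are unaffected
by the fate of unrelated features. The ceiling in the sample rule means a
fractional requirement is never satisfied by rounding down.

## Hierarchy

A family (order, class, phylum) is scored with the aggregated abundances of
its child-rank subgroups as members. Features unannotated at the child rank
are dropped from the aggregation so that abundance from two different
unknown lineages is never pooled, and single-subgroup groups are skipped.
Aggregation is a plain sum, so conservation — group abundance equals the sum
of subgroup abundances over contributing features — holds to machine
precision, and a group's score is invariant to any redistribution of
abundance *within* a subgroup. Ranks are scanned bottom-up and the group
filter is re-applied independently at each rank. Subgroup-count eligibility
is assessed after abundance filtering.

## Turnover

For each (subject, group) pair, time points are ordered and the winner
called at each point with the standard cutoff; time points whose group
abundance is at or below the 0.5% floor carry no evidence. A pair is
eligible with at least two above-floor time points, and turnover is declared
when two such points name different winners — an existential predicate, so
reverting to the initial winner still counts and the result is invariant to
time reordering.

## Synthetic data

The generators define the conditions under which the pipeline is validated:

* **Group allocation** (first step): symmetric Dirichlet over groups,
  concentration 1 by default (uninformative); longitudinal fixtures use
  concentration 5 so that group abundances rarely fall below the
  eligibility floor and planted events are expressed.
* **Lottery schema**: winner drawn from a categorical winner distribution
  (uniform unless specified), winner fraction ~ Uniform(0.92, 1.0) — chosen
  strictly above the 0.9 cutoff so noise-free lottery samples always carry a
  detectable winner — and losers share the remainder by a GEM(θ = 1)
  stick-break (heavy-tailed, resembling observed residual abundances), with
  a symmetric-Dirichlet option. Loser shares are randomly permuted so share
  size is not tied to member identity.
* **Fixed winner**: the lottery schema with a point-mass winner
  distribution.
* **Coexistence**: symmetric Dirichlet over members with concentration 10 —
  even sharing with realistic fluctuation, under which a 0.9-dominant member
  is vanishingly rare.
* **Stick-breaking nulls**: GEM (sequential Beta(1, θ) breaks, remainder to
  the last piece) and the classic broken stick (uniform cut points). For
  the two-piece broken stick, P(max fraction > 0.9) = 0.2 exactly, which
  anchors the Monte-Carlo checks.
* **Poisson noise**: counts drawn independently per feature as
  Poisson(abundance × depth); total depth therefore varies around the
  nominal value. Depth 5000 mirrors the read floor used in the filters.
* **Longitudinal series**: per subject, lottery winners persist across time
  except at planted switches (probability = the turnover rate, switch time
  uniform over interior time points, new winner drawn from the remaining
  members). The planted log records both the generative switch and the
  *expressed* ground truth — whether distinct realized winners actually
  occur at two above-floor time points — because a switch planted while the
  group is below the floor is invisible to any detector. Noise-free,
  detection equals expressed truth exactly.
* **Gene counts**: per-species totals ~ round(Normal(class mean,
  dispersion)), KO-annotated share Binomial(total, 0.7). The planted-effect
  condition (lottery mean 2000 vs non-lottery 4000, sd 300, 10 species per
  class) gives the rank-sum test essentially full power at α = 0.005.

What the generators do **not** emulate: cohort-specific effects (sample
preservation, primer and pipeline bias), compositional coupling between
groups beyond the Dirichlet allocation, phylogenetic correlation of
schemas, or strain-level structure below the feature level. Passing tests
therefore demonstrate correctness of the statistics under the model's own
assumptions, not that real cohorts satisfy those assumptions.

## Numerical choices

* Entropies use log base 2 with 0·log 0 := 0; `np.log2` is exact on powers
  of two, so the analytic anchor cases (uniform winners → diversity exactly
  1; uniform members → prevalence exactly 0) hold without tolerance.
* Ties for "most abundant member" are broken lexicographically by member
  id; display-ordering ties (block size, within-block fraction) fall back
  to lexicographic ids — determinism for regression tests.
* The `top_k` restriction keeps, by default, each **sample's** k most
  abundant members and renormalizes. This makes "restriction can only raise
  the maximum fraction, hence prevalence" a theorem, since the sample's
  dominant member is always retained; ranking by mean abundance across
  included samples (the other natural reading of "the k most abundant
  members of a group") is available via ``top_k_ranking="mean"`` but does
  not guarantee monotonicity, because a member that wins a single sample
  can be globally rare.
* Within-group fractions in a zero-abundance sample are undefined; such
  samples are excluded (a signal, not an exception). An all-samples-excluded
  group is an error.
* Cross-dataset comparison uses `scipy.stats.spearmanr`; the gene-count
  comparison uses a two-sided Mann-Whitney rank-sum test (robust to the
  skew of gene-count distributions), with Welch's t behind a flag, and no
  multiple-testing correction across the three gene-count fields (raw
  p-values are reported and labelled as such).

## Problem sizes

The validation suite and `scripts/acceptance.py` use synthetic communities
of 10 groups × 5 members at 1000 samples for schema recovery, 200 random
tables of at most 15 features × 100 samples for brute-force oracle
equivalence, 100k replicates for the broken-stick Monte-Carlo, 30k
replicates per grid point for the Poisson sweep, and 500–1000 replicates
for the gene-count calibration — sizes at which every Monte-Carlo check has
standard error well inside its assertion band.

## Known limitations

* Taxonomic grouping inherits the reference taxonomy's defects; polyphyletic
  genus names are treated as a single group.
* The winner cutoff, inclusion floors, and classification thresholds are
  conventions, not estimates; the sensitivity-sweep operations exist to
  show how conclusions move with them.
* No statistical significance is attached to prevalence/diversity values —
  they are descriptive, and small included-sample counts make them noisy.
* The BLAST/IMG step that maps features to reference genomes is represented
  only as the gene-count input contract; no alignment is performed.
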