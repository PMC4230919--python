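# Methods

## The detection model

A clone library is modelled as `n` independent draws from an egg capsule in
which a non-target taxon occurs at incidence `q` (the proportion of the
capsule's amplifiable template belonging to that taxon). The probability of
observing it at least once is `P = 1 − (1−q)^n`; solving for `q` at a chosen
confidence gives the largest incidence compatible with zero detections,
`q_max = 1 − (1−P)^(1/n)`, and the smallest sufficient library size is
`n = ceil(log(1−P) / log(1−q))`. The expected number of clones to a first
detection is the geometric mean `1/q`.

Assumptions, stated where the numbers are reported: equal incidence of the
non-target taxon across all capsules and hosts, no amplification bias during
PCR, and independence between clones. Under these assumptions clone counts
pool additively, so the combined row of an incidence table uses
`n = Σ n_host`. Violations (PCR bias, patchy incidence between capsules)
make the pooled bound optimistic; the simulator's optional per-capsule
Beta-distributed incidence (`q_concentration`) exists to explore that, but
is off by default because the model is tested under its own assumptions
first.

Numerics: all forms go through `log1p`/`expm1`. The naive `(1−q)**n` loses
all precision for small `q` and large `n` (and saturates to exactly 1.0 in
doubles once `n·q ≳ 37`, where the inversion is inherently ill-conditioned —
the property tests restrict round-trip identities to `P ≤ 0.999` for this
reason). `required_clones` guards the `ceil` against floating-point boundary
slips with a two-sided local scan.

Rounding: reported tables round half away from zero (3 decimals for
incidence tables, 2 for percent distance ranges); machine-readable outputs
always carry the full-precision values alongside. The published per-host
values this package reproduces mix truncation and rounding in their last
digit (printed 0.156 and 0.601 where the closed form gives 0.15681 and
0.60189), so comparisons in the tests allow one unit in the last printed
digit.

## Distances and masking

Uncorrected ("p") distance: mismatches over comparable sites, where a site
is comparable only if both residues are unambiguous bases (A/C/G/T). Gaps
and IUPAC ambiguity codes are excluded per pair (pairwise deletion), never
scored as partial matches — compatible codes (e.g. R vs A) are excluded
outright rather than weighted, since any weighting would be arbitrary. A
pair with zero comparable sites raises an error; silently reporting 0 or NaN
would corrupt downstream minima.

Masks (removal of ambiguously aligned regions) are inputs, given as 0-based
retained-column indices internally and 1-based inclusive ranges in files and
reports. No automatic mask inference is attempted.

Group range tables report min–max percent distances per pair of groups;
within-group cells exclude self-pairs and are NA for singleton groups.

## Synthetic surveys

The generator emulates the survey design the analysis assumes: sites ×
hosts × capsules, each capsule yielding `clones_per_capsule` sequences; each
clone is independently a contaminant with probability `q`, and target clones
copy a subclade reference chosen by a per-capsule mixture, then receive
independent per-site substitutions at `error_rate` (uniform over the three
alternative bases, so the expected clone-to-reference p-distance equals
`error_rate` exactly).

Reference panels hit a requested pairwise divergence matrix by construction:
the matrix is fitted to a neighbor-joining topology with non-negative least
squares on the path/edge incidence system, each edge receives
`round(length × L)` mutations at globally disjoint columns, and leaf-to-leaf
divergence is then exactly the path sum. A matrix that is not tree-additive
within 20% relative error, or whose rounding error at the chosen `L` exceeds
that band, is rejected with a constructive message (the default matrix needs
`L ≳ 300`). Defaults follow the observed scale: close pairs I–II at 1.2% and
III–IV at 1.6% (midpoints of the observed 0.65–1.72% and 1.37–1.88% ranges),
all cross pairs at 3.7%.

Contaminant ("NON_TARGET") clones are placed at ≥10% divergence from every
reference. The real system does not pin this value down; 10% is a repo
convention chosen to be far outside the subclade scale while leaving most of
the sequence intact.

The default survey design mirrors the study's per-host clone totals
(85/27/9/5 across four hosts) with the observed host–subclade associations,
and `q = 0` — the real survey observed no contaminant; tests and power
analyses raise `q` explicitly.

No indels, chimeras, rate heterogeneity, or tree-structured within-subclade
evolution are simulated. Synthetic alignments are therefore gap-free, with
i.i.d. clones per capsule — exactly the detection model's own assumptions.
Passing tests on this generator validate the statistics under those
assumptions; they say nothing about alignment quality, PCR bias, or chimeric
reads in real libraries (gap and ambiguity handling is covered by hand-built
fixtures instead).

Randomness: one integer seed per survey; each capsule's generator is derived
from `(seed, crc32(capsule_id))`, so outputs are independent of generation
order and stable across runs.

## Classification

Nearest-reference assignment by p-distance with a hard threshold: the
default 0.02 sits between the within-subclade scale (clone noise plus the
closest reference pairs, ≤ 1.9%) and the between-subclade scale (≥ 2.97%).
Distance ties break by lexicographic group label and are reported with
margin 0 so callers can detect them. Clones farther than the threshold from
every reference are UNASSIGNED and appear as their own group in composition
tables, so per-site fractions always sum to 1. This stands in for tree-based
subclade reading; it is only as good as the separation between the scales,
and is validated on synthetic data with between-divergence ≥ 3%.

## Trees

Neighbor-joining with the standard Q-criterion; ties broken by the
lexicographically smallest pair of cluster ids (a cluster is identified by
its smallest leaf label), making topologies deterministic. Negative limb
estimates are clamped to zero with the deficit moved to the sibling edge,
preserving the joined pair's path length; zero-length internal edges are
collapsed rather than reported as arbitrary resolutions. On additive
matrices NJ recovers the generating tree exactly (tested against matrices
built by construction and against scikit-bio's implementation).

Bootstrap: alignment columns are resampled with replacement after masking
(inference always runs on the masked matrix); supports are the percentage of
replicate NJ trees containing each internal split of the point tree,
reported as integer percent on internal node labels. Replicates that lose
all comparable sites for some pair are discarded with a warning; more than
10% discarded aborts. NJ bootstrap values are not comparable to published
likelihood/parsimony supports; the package exports PHYLIP matrices and
alignments for external ML/MP software rather than re-implementing it.

## Problem sizes in the shipped tests

The test suite simulates at reference length 400–1250 and 24–126 clones per
survey, 100 bootstrap replicates, 20 seeds for structure recovery, 500
replicates for coverage checks, and 10^5 Monte Carlo libraries per oracle
trial — sizes at which every statistical check has comfortable power while
the whole suite stays desk-scale.
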