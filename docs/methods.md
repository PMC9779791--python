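# Methods

## Product-score model

Crosstalk from sender cluster i to receiver cluster j through a
ligand–receptor pair L–R is scored as E_L,i · E_R,j, where E_g,k is the
arithmetic mean of the CP10K-log1p normalized expression of gene g over the
cells of cluster k. The model assumes communication intensity is monotone
in both the sender's ligand output and the receiver's receptor
availability; it ignores spatial proximity, secretion efficiency and
multi-subunit receptor complexes (the database is binary pairs). Autocrine
signaling (i = j) is scored like any other pair.

Averaging is done in log space by default: log-space means are robust to a
few extreme cells, which matters because the product amplifies sender-side
and receiver-side errors multiplicatively. Whether cluster averaging should
happen in log or linear space is genuinely open; both are implemented
(`space="log"` / `"linear"` in `cluster_means`) and only the default
differs.

## Permutation null

Significance of an observed product is empirical: cluster labels are
permuted uniformly over cells — cluster sizes preserved, expression
untouched — the E values recomputed, and null products compared against the
observed one. "More extreme" is one-sided (null ≥ observed) by default
because the score is a non-negative association measure and the question of
interest is enhanced crosstalk; a two-sided option is exposed
(`tail="two_sided"`). The Monte-Carlo estimate uses the add-one convention
p = (1 + #{null ≥ obs}) / (n_perm + 1), a valid permutation p-value that is
never zero. When the number of distinct label assignments is ≤ 10^5
(`exhaustive=True`), all assignments are enumerated and p is the exact tail
fraction with the identity assignment included in both numerator and
denominator, so again p > 0. The enumeration doubles as the independent
oracle for the Monte-Carlo path in the tests.

When profiles are stratified by condition the shuffle must stay within the
stratum — the null has to preserve the design — which falls out naturally
here because each stratum is scored in a separate call on its own cells.
Whether the shuffle should additionally preserve per-sample structure is
not settled; the default shuffles within condition only.

p-values are reported raw, with BH-adjusted values within each
(sender, receiver) family alongside. Detection rules in the package default
to raw p, since the aggregate definition itself involves no multiplicity
correction.

## Aggregate and differential crosstalk

The overall crosstalk level from i to j is Σ_L Σ_R E_L,i E_R,j over pairs
with product strictly greater than θ; θ = 1.5 on the CP10K-log1p scale, and
significance is *not* required for a pair to enter the aggregate (the
`require_significant` flag adds the p ≤ α condition for sensitivity
analyses). Entries are therefore non-negative and non-increasing in θ,
properties the tests check over a θ grid.

Differential crosstalk subtracts per-pair products between conditions
(degenerated − normal) on the common cluster set. Because "high in a
condition" needs a numeric rule, the package uses an explicit band:
call = high_in_degenerated iff difference ≥ δ and the degenerated score
> θ (symmetrically for normal), else unchanged; δ = 0.5 by default and
configurable. Calls are then counted per functional category of the
database (ECM, TNF, TGFB, chemokine, cytokine, antigen_presentation,
other).

## Quality control

Per-cell metrics are n_counts (UMI), n_genes (observed genes), percent_mito
and a dissociation score defined as the percentage of counts from a
dissociation-stress gene list. Doublet scores are consumed as externally
computed metadata in [0, 1]; computing them is out of scope.

Threshold filtering resolves `"auto"` to the 99th percentile of each
metric's distribution, except max_percent_mito which is additionally
floored at an absolute 20%: below that, mitochondrial variation is within
the normal biological range and an upper-percentile cut would discard ~1%
of healthy cells in every clean dataset. Lower bounds default to
min_n_genes = 200 and min_n_counts = 500. All thresholds are overridable;
filtering with a fixed, resolved threshold set is idempotent, and loosening
any single threshold never removes additional cells.

Tiny-outlier-group flagging captures the divide-and-conquer observation
that subclustering acts like a centrifuge, concentrating low-quality cells
into small groups: a cluster is flagged when its size fraction is ≤ 2% of
the dataset and its median doublet score, percent_mito or dissociation
score exceeds the 95th percentile of all cells. Flagging is advisory —
removal is the caller's decision — and a small allow-list-style workflow
(e.g. keeping a cycling population despite its size) is supported simply by
not dropping a flagged group. Iterating recluster → flag → remove is left
to external tooling since clustering itself is outside the package.

## Normalization and differential expression

Normalization is counts-per-10,000 followed by natural log1p, recorded in
the matrix provenance so alternative conventions remain pluggable.
Zero-count cells are a hard error pointing back at QC.

Marker and condition contrasts use the two-sided Wilcoxon rank-sum test per
gene: exact null when either side has ≤ 8 observations and the gene is
tie-free, normal approximation with tie correction otherwise, p = 1 for
completely tied genes. Genes expressed in < 10% of cells on both sides are
skipped; BH adjustment runs over the tested genes of one contrast. Fold
changes are log2 ratios of expm1-means with a 1e-9 pseudocount. This is a
deliberate rank-sum stand-in for the marker machinery of the large
toolkits; numerical parity with any of them is a non-goal.

Composition statistics compute per-sample cell-type percentages (summing to
100 within a sample) and compare conditions per cell type with a two-sided
Wilcoxon rank-sum: exact when ≤ 20 samples and tie-free, asymptotic
otherwise, NA with a warning when a condition has fewer than two samples.

## Synthetic data: what it emulates, and what it does not

The generator draws counts from a negative binomial with shared dispersion
(r = 2) — the standard overdispersed count model — with a per-cell
log-normal library-size multiplier (σ = 0.3, mean 1) so CP10K
normalization is doing real work. Structure on top of the background:
per-cluster marker genes (fold 3), planted ligand/receptor elevations
(fold f in sender/receiver, optionally condition-specific; f = 1 encodes a
null pair), per-condition composition shifts, two condition groups with
three samples each (so the composition Wilcoxon has replicates) assigned
round-robin to zones, and planted low-quality cells. Bad cells re-partition
the cell's expected expression so the mitochondrial (or stress-gene) share
reaches 50% (40%) while total depth is unchanged — i.e. the *fraction* is
pathological, not the library size — and planted doublets receive a
doublet score of 0.9 against a Uniform(0, 0.3) background, emitted directly
as metadata rather than via simulated barcode collisions, because the QC
layer consumes scores, not droplets. With `isolate_bad_clusters` the bad
cells surface as their own tiny labeled groups, emulating the subclustering
centrifuge that the group-flagging rule expects.

Default conditions were calibrated once, at design time: 2000 genes with
baseline NB mean 0.6 give a median depth ≈ 1200 (safely above the QC
floors) and put background cluster means near E ≈ 1.0 on the CP10K-log1p
scale, so background products sit around 1.0 — below θ = 1.5 — while fold-4
planted pairs yield products ≈ 5–6. That is the regime in which a fixed θ
meaningfully separates signal from background; 5 clusters × 200 cells per
condition and a 200-pair database (one-to-one ligand–receptor pairing, so a
planted pair perturbs no other database pair) are the standing test
conditions. The generator does not model ambient RNA, UMI saturation,
batch chemistry, spatial coordinates, or gene–gene correlation beyond the
planted structure — so passing tests demonstrate correct recovery of the
planted statistical structure, not robustness to every artifact of real
droplet data.

## Numerical and reproducibility choices

Everything is deterministic given the seeds: the generator from `SimSpec.seed`,
the permutation null from `CrosstalkParams.seed`. The pipeline fans a
single global seed out by a fixed counter scheme (simulate: seed; crosstalk
stratum t in sorted condition order: seed + 1 + t) so stages can be rerun
independently; two runs under one config produce byte-identical outputs,
and the run manifest records every output file with its SHA-256. Aggregate
thresholding is strict (> θ); θ = +inf yields the zero matrix. Problem
sizes in the test suite and acceptance script (≈ 1000–2000 cells, 200
pairs, 500 permutations) were chosen as the smallest at which the planted
effects and calibration properties are stable.

## Known limitations

Gene identity is by exact symbol; no alias or ortholog resolution. No
multi-subunit complexes or agonist/antagonist annotations. The permutation
null conditions on cluster sizes but not on per-sample composition. Planted
"spillover" — a truly elevated ligand read against a non-planted receiver —
is genuinely detected by the score-and-p rule and accounts for the ~3%
false-positive rate against planted-tuple ground truth; this is a property
of the product-score model, not an implementation artifact.
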