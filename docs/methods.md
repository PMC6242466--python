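# Methods

`hdscreen` analyses pinned colony-array chemical screens: arrays of yeast
strains grown as colonies under a control and a drug condition, photographed
over days, and scored for strains whose growth responds to the drug. This
note records the models, the parameter choices and their rationale, and the
known limits of what the synthetic benchmarks demonstrate.

## Colony quantification

A plate image is reduced to one *integrated density* per grid position:

1. **Grid estimation.** Colony-like connected components above the
   background cut are located, and nearest-neighbour displacement vectors
   between component centroids give the row/column pitch and the rotation
   of colony rows relative to the image frame. Grid indices are then fitted
   by least squares to recover the top-left colony center. A manual anchor
   (`x, y, angle`) overrides the estimated origin and angle exactly; pitch
   is always estimated. Plates with fewer than ~5% of the expected colonies
   raise a grid-detection error rather than guessing.
2. **Colony measurement.** Around each predicted center, the center of
   gravity of above-background intensity in a 17×17 window seeds the
   measurement. From that pixel the four cardinal directions are walked to
   the first background pixel; the midpoint of the bounding box re-centers
   the colony, and one further walk gives the final center and the four
   border distances. The oval with semi-axes `(left+right)/2` and
   `(up+down)/2` is scored as integrated density = mean intensity × area
   (area = πab, the identity holds to machine precision). Windows with no
   pixel above the cut yield a missing measurement with zero density; walks
   that hit the 40 px cap or the image edge flag the measurement.
3. **Background model.** Background is estimated per plate as the median of
   pixels in the inter-colony margins (farther than 0.35 pitch from every
   grid line); a pixel is background iff its intensity ≤ level + k·spread
   with robust spread (1.4826·MAD) and k = 3. The cut is floored at
   level + 0.5 — half a gray level of an integer-valued image — so that on
   an exactly noise-free plate (spread = 0) vanishing colony tails still
   count as background. Mean density is *not* background-subtracted by
   default (the log/quantile/LOESS chain absorbs the offset); subtraction
   is available behind a flag.

Two centering/walk iterations are performed; the count is configurable.
Coordinates are 0-based pixel indices, `(x=col, y=row)`, top-left origin.

## Normalization

Raw densities are log2-transformed (configurable pseudocount, default 1).

**Quantile normalization** forces the replicate columns within each
(condition, day) onto their common distribution: each column's value at
rank r becomes the across-column mean of the rank-r values. Ties receive
the mean of the tied-rank targets; missing values are excluded from ranking
and restored. The step is idempotent and leaves sorted columns identical to
1e-9. It removes plate-to-plate technical shifts, which the simulator
injects as one additive log2 draw per physical plate.

**Cyclic LOESS** corrects the colony-size-dependent basal effect of the
drug. For each matched plate pair (default: the control and drug plates of
the same replicate and day), a local regression of M = x_drug − x_control
on A = (x_drug + x_control)/2 estimates the size-dependent trend, which is
split antisymmetrically (half subtracted from one column, half added to the
other, scaled by the number of pairs a column participates in), preserving
the per-pair grand mean. Cycles repeat until the summed absolute correction
falls below `epsilon` (default 1, in summed log2 units — the printed value
of the source pipeline, whose unit is not stated there) or `maxit` = 5
cycles. Span is 0.05.

The local regression is degree-1 with tricube weights and **two robustness
re-weighting iterations**. Robust (symmetric-family) fitting is the default
of the normalization tool this stage models, and it matters in practice:
on a simulated sharp size-dependent offset (0.5 log2 for colonies below the
median size, n = 1000), a non-robust fit under 5 cycles leaves a residual
rank correlation of |ρ(M, A)| ≈ 0.08 between difference and average, while
two robust iterations reduce it below 0.001. `robust_iterations = 0`
restores the plain fit.

## Differential testing and hit calling

With four replicates, per-strain variances are too unstable for a plain
t-test. The regularized (empirical-Bayes) test shrinks each strain's
variance toward a background estimated from strains of similar mean
density: strains are ranked by mean normalized density and the background
variance σ₀² is the mean sample variance over a 101-strain window centered
on each strain (truncated at the ends; a window spanning all strains yields
the global mean). The posterior variance per group is

    σ̃² = (conf·σ₀² + (n−1)·s²) / (conf + n − 2)

with `conf` = 15 prior pseudo-observations, so the neighbours dominate at
n = 4. The statistic is Welch-style, t = Δ/√(σ̃²_c/n_c + σ̃²_d/n_d), with
df = n_c + n_d + 2·conf − 4 by default (each group contributes n + conf − 2
effective degrees of freedom; plain n_c + n_d − 2 is available — the source
describes `conf` as adjusted degrees of freedom without printing a
formula). Each day is tested independently; p-values are BH-adjusted per
day; a strain is a hit when its adjusted p < 0.01 on at least two days
*with a consistent sign* of the drug − control difference (equal counts in
both directions leave the strain uncalled, keeping the increased/decreased
hit sets disjoint). Strains missing more than one replicate in either
condition are excluded from that day. The 0.01 threshold applies to
adjusted p-values by default; raw-p thresholding is a flag.

## External-dataset comparison

Five compilation rules mirror the five study categories: deletion-fitness
calls (±1/0) are summed across sources; mRNA changes are averaged across
the sources that measured each gene; protein-abundance sources are each
divided by their own SD and summed; flux sources contribute the sum of
absolute Z-scores over the per-compartment/timepoint top-100 lists (genes
in no list score 0); phosphoproteomics mixes qualitative ±1 calls with
SD-normalized quantitative sources.

Overlap between two ranked datasets is the one-sided hypergeometric p of
the intersection of their top 1, 5, 10, 15, 20 and 25% (floor rounding,
minimum one gene), within the universe of genes present in both; the
smallest p over the grid is reported uncorrected (a Bonferroni-corrected
companion value is attached). Screen strains are ranked by best per-day
p-value ascending, ties by |Δ| descending then strain ID; signed mode runs
from the most significant decreased strain through non-significant strains
to the most significant increased strain.

**Running-overlap curves** smooth the binary top-set membership indicator
along a ranking with a degree-0 uniform-weight local regression — a running
mean over a window of half the ranking length, truncated at the ends. The
degree-0/uniform choice is deliberate: the curves are running *averages* of
membership, an unbiased local estimate whose supremum deviation on a random
top set stays within the binomial band around the base rate (measured
median sup-deviation ≈ 0.03 at n = 1000, |top| = 200). Tricube degree-1
smoothing at any span inflates the supremum above ±0.05 through boundary
slope noise and kernel variance inflation. The span is configurable.

## Enrichment statistics

Over-representation uses the one-sided hypergeometric test. The conditional
DAG-aware variant tests terms leaves-first (reverse-topological order,
sibling ties broken lexicographically); when a term is significant
(p < 0.05), its annotated genes are excluded from the annotations of all
its ancestors before those are tested, so the most specific enriched terms
survive. The universe itself is left untouched by conditioning — only the
ancestors' gene lists shrink — and defaults to the screened strain set.
Annotations are propagated child→ancestor before testing, and the
propagation is validated. No FDR is applied across terms by default
(matching the conditional procedure's convention); a BH column is optional.

Enriched terms form an enrichment-map graph: unordered term pairs with
Jaccard coefficient strictly greater than 0.25 become edges weighted by the
coefficient. The graph is exported (TSV/GraphML); layout is the consumer's
concern. The module also provides the Pearson chi-square test of
independence for 2×k tables and the GWAS-homolog overlap test, which
filters SNP records to case-control studies with association p < 1e-5,
collapses them to per-disease yeast gene sets through a supplied homolog
table, and applies the hypergeometric test per disease.

## Synthetic screens

The generator works on the log2 integrated-density scale:

    log2 density = baseline + growth(day) + plate effect
                   [+ basal(baseline) + effect, on drug] + noise

with per-strain baseline ~ N(10, 1) log2 units, saturating day growth
3·day/(day + 2) log2 (colonies roughly 8× denser by the last imaging day),
one N(0, 0.05) technical shift per physical plate (constant across that
plate's imaging days), N(0, 0.15) replicate noise, and a logistic basal
drug penalty of amplitude 0.5 log2 centred at the baseline mean (small
colonies are hit hardest — precisely the structure cyclic LOESS removes).
Default screens have 3,504 strains × 4 replicates × 2 conditions × 9 days
(days 1–5, 7, 10, 12, 14) in 1,536 format (3 plates per replicate);
5% of strains carry a true ±0.5 log2 drug effect on every day. The noise
magnitudes are choices of this package — the real screen's are not
published — and are tunable.

Rendered plates draw each colony as a radially smooth super-Gaussian disc
(`exp(−(r/σ)⁴)`) whose scale grows with √density, so peak intensity is
density-independent until the radius cap (0.30 pitch) bites; each colony's
pixel sum above background equals its table density exactly. Images are
16-bit grayscale PNG/TIFF.

Matched external datasets draw `score = corr·z + √(1−corr²)·noise` from the
standardized truth for continuous categories; deletion calls agree with the
truth's sign with probability (1 + corr)/2; flux lists are per-list
top-100 selections on a correlated latent score. Toy ontologies are random
rooted DAGs with genes annotated on leaves and propagated upward.

**What the synthetic benchmarks do not show.** Real plate photographs have
vignetting, agar texture, reflections, smeared or merged colonies and
non-elliptical morphologies; the renderer has none of these, so passing the
quantification checks demonstrates correctness of the measurement
procedure, not robustness to imaging artefacts. Real biological effects are
not uniform shifts on all days, real external datasets are not Gaussian
transforms of a shared truth, and real ontologies are far deeper than the
toys; the corresponding checks validate the statistics, not biological
fidelity.

## Problem sizes and numerical choices

The test suite and the acceptance script use full 3,504-strain screens for
the error-control and recovery checks, 3 noiseless 1,536-format plates for
quantification fidelity, n = 1000 pairs for normalization residuals, 50
seeded trials for overlap discrimination, and 1,000 random hit-set draws
for the conditional-enrichment type-I rate — sizes chosen to match the
study conditions while keeping a full run in minutes on one CPU. Degenerate
inputs are handled explicitly: constant-A plate pairs are skipped with a
warning, zero-variance strains with zero difference give t = 0/p = 1 (an
exact nonzero difference with no variance gives p = 0), sub-2-replicate
groups are excluded, and empty ontology terms are dropped from the map
with a warning. All randomness flows from explicit seeds; identical seeds
reproduce every table byte-for-byte.
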