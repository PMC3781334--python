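# Methods

## Model and procedure

`stressclust` analyzes a 2 × 2 × 2 factorial expression study — genotype
(WT / KO for an ER-stress sensor), treatment (vehicle / tunicamycin), time
(8 h / 34 h) — with replicate animals per condition group. The analysis is
deliberately categorical: instead of fitting a joint model, each gene is
summarized by four three-state calls and genes are grouped by the exact
tuple of calls. This trades statistical efficiency for interpretability
and transparency of the bottom-up procedure; the groups are then
interrogated independently by pathway and motif over-representation.

### Three-state calls

For a comparison with numerator replicates *a* and denominator replicates
*b* (strictly positive, linear scale):

* log2FC = log2(mean(a) / mean(b)). Means are taken on the linear scale;
  a `log_means` flag switches to the difference of mean logs. The ratio
  of group averages is the default convention.
* Pooled-variance two-tailed Student *t* with n_a + n_b − 2 df
  (`welch=True` available). Zero pooled variance is a documented
  convention: equal means → (t = 0, p = 1); unequal → (±∞, 0). This makes
  the noise → 0 limit of the synthetic data well defined.
* Call: `up` iff log2FC ≥ τ and p < α; `down` iff log2FC ≤ −τ and p < α;
  else `unchanged`. τ = log2(1.5) exactly (≈ 0.5849625; 0.58 is
  its two-decimal rounding) and the boundary is inclusive, so an exact 1.5-fold
  change with small p is called. α = 0.05 for profile calls; the
  first-suppression timing utility uses the relaxed α = 0.1 tier.
* No multiple-testing correction is applied to per-gene calls — fidelity
  to the categorical procedure; FDR control enters only at enrichment.

`first_suppression_time` reports the earliest time with a down call and a
`sustained` flag that is False when the immediately following time point is
not also down (a transient dip of ambiguous timing); a down call at the
final time point counts as sustained, since no later evidence exists.

### Profiles and groups

81 = 3⁴ profiles; the c4 ≠ `unchanged` filter leaves 54. The named groups
map to tuples (order c1, c2, c3, c4; `nc` = unchanged):

| group | tuple | | group | tuple |
|---|---|---|---|---|
| A | nc,nc,nc,up | | F | down,nc,down,down |
| B | nc,nc,nc,down | | G | nc,nc,down,down (inferred) |
| C | up,nc,nc,up | | H | up,up,up,up (inferred) |
| D | down,nc,nc,down | | I | nc,nc,up,up |
| E | up,nc,up,up | | ATF6 | up,down,up,down |

G and H have no canonical tuple definition; the defaults are inferences —
G by symmetry with I among the down-groups, H as the sustained-up profile —
and are flagged `inferred=true` in every output and overridable in the
taxonomy. Unlabeled genes that survive the c4 filter are tallied under
their raw profile id, so the full 54-way breakdown is always emitted.

Probeset collapsing operates on *calls*, not intensities: the modal profile
per gene wins; ties break to (i) the profile with more regulated calls,
then (ii) lexicographic order with down < unchanged < up per position, and
tie-break events are logged.

The display heatmap anchors every column on vehicle-treated WT at the same
time point, so the KO columns compound the WT effect with the genotype
difference (a group-F gene at effect 1.5 reads (−1.5, −1.5, −1.5, −3.0)),
while the c2/c4 *call* criteria compare KO-TM to WT-TM. Both conventions
are implemented explicitly and never mixed.

### Pathway enrichment

Exact hypergeometric upper tail P(X ≥ k) (scipy, no normal approximation)
per (group, pathway), BH step-up FDR within each group (a joint-FDR flag
exists; per-group is the default because each group is reported as its own
analysis). The universe is the set of genes on the matrix after
collapsing — array-practice, not genome-wide — and is configurable. No
term decorrelation is attempted (some enrichment tools decorrelate GO
terms by proprietary schemes); the standard exact test keeps the
computation transparent and affects p-values but not which planted
pathways dominate. The top-7 report
selects by q (ties: p, then pathway id), filters q < 0.05, then reorders
descending by hit count.

### Motif enrichment

PWMs are JASPAR PFM text (both the bracketed and bare 4-row dialects);
log-odds use a total pseudocount of 0.8 split by background base
frequencies, which are estimated from the supplied promoter set by default.
Scanning slides both strands across the ±2000 bp TSS window; the relative
score (score − min)/(max − min) must reach the threshold (default 0.85, the
conventional single-site setting; configurable). Windows crossing non-ACGT
characters score −∞ (no hit through them); coincident opposite-strand hits
at one start position collapse to the higher-scoring strand (ties → '+').

Per factor, with x target hits, background rate r = background hits /
background scanned positions, μ = r · target positions and
σ = √(μ(1 − r)): Z = (x − μ − 0.5)/σ (binomial model with continuity
correction — a deliberate simplification; single-site tools vary in
their exact count model), plus a one-tailed Fisher exact test on
genes-with-≥1-hit, target vs. rest of background. Pass thresholds default
to Z > 10 and Fisher p < 0.01. σ = 0 reports a null Z with a reason rather
than a value. No conservation/phylogenetic-footprinting filter is applied
(determinism; the interface leaves the hook). The background gene set is
caller-supplied — there is no silent default universe.

### Validation statistics

Percent input = 100 · 2^(adjusted − Ct_ip) with adjusted = Ct_input −
log2(1/input_fraction); 100% amplification efficiency is assumed. One-way
ANOVA wraps the classic between/within F with the conventions F = 0, p = 1
for all-identical input and F = ∞, p = 0 for zero within-group variance
with unequal means; the two-group case reduces to t² exactly.

## The synthetic generator

The generator *is* the study conditions: 8 condition groups × 3 replicates,
600 genes of which 10 groups × 30 carry planted profiles and 300 are an
unregulated null pool, planted |log2FC| = 1.5, replicate noise log-normal
with CV = 0.10 (sd on log2 scale = log2(1 + CV), the standard
intensity-scale error model for array data), gene baselines
~ N(7, 1.5²) on the log2 scale (typical microarray intensity range).
Effects compose along the comparison chain (KO-TM mean = WT-TM mean + c2/c4
effect), so each comparison reads back exactly its planted signed effect as
noise → 0. Doses are not modeled; effects are planted per comparison
directly, since dose never enters the computational procedure.

Promoters are 4001 bp (TSS centered, so the full ±2000 bp window exists),
i.i.d. background at configurable GC (default 0.25/base). The built-in PWM
set has three planted factors (an NF-Y analogue for the ATF6 group, an
HNF4 analogue for B/D/F, an ETS analogue for A/C/E) and two never-planted
decoys; matrices are 14 bp with 97/1/1/1 columns. That sharpness is a
design choice made once, up front: sampled sites then score above the 0.85
relative threshold ≥ 99% of the time while random hits stay ~2·10⁻⁶ per
position, which at 2 sites per planted promoter, planting rate 0.9 and
30-gene groups in the 600-gene universe puts the planted factor at Z ≈ 15–30
against the fixed Z > 10 cutoff and leaves decoys near Z ≈ 0. Softer, more
realistic JASPAR-like matrices would need larger gene sets to clear the
same fixed cutoff; the generator documents this rather than hiding it.
Planted sites never overlap (rejection sampling) so the truth table is
unambiguous for scanner tests.

Annotations: each named group gets one planted pathway whose members are
drawn *only* from that group at rate fold × background (default 5 × 0.05),
plus 20 background pathways annotating all genes at 0.05. A fold of 1
makes the planted within-group rate match background in expectation.

What the generator does **not** emulate: probe-level intensities and
normalization artifacts, batch effects, correlated noise between genes,
dose–response, basal genotype differences, realistic promoter composition
(CpG islands, repeats) and soft JASPAR motifs. Passing recovery tests
therefore demonstrate that the pipeline's inference chain is correct under
its stated assumptions — not that those thresholds would perform
identically on real arrays.

## Problem sizes and numerics

The shipped tests and the acceptance script run the generator at its
default size (600 genes) — 20 simulations for profile recovery, one for
the scanning/enrichment recoveries — sizes at which every planted effect is
comfortably detectable and a full run completes in seconds. The noise → 0
limit is exercised at CV = 10⁻¹² rather than exactly 0 (the config requires
positive CV); the zero-variance t-test conventions cover the exact-0 case.
Floating tolerances: planted-ratio checks at 1e-9, noiseless heatmap rows
at 1e-6 (residual 1e-12 CV), exact-test oracles at 1e-12. Determinism:
every stochastic step uses `numpy.random.default_rng` seeded from the
config; the promoter and annotation generators derive fixed offsets
(seed+1, seed+2) so the four generators are independently reproducible, and
the pipeline manifest records sha256 checksums per output.

## Known limitations

* The categorical caller has no variance moderation; genes with tiny
  replicate variance can reach significance at small fold changes on real
  data (not in the planted designs, where effects are ≥ τ by construction).
* The Z-score's binomial model ignores overlap between scan windows;
  for sharp motifs the effect is negligible, for soft motifs it inflates σ
  slightly.
* The enrichment stage does not propagate ontology structure (no DAG
  ancestry, no term decorrelation): terms are treated as flat sets.
* Group G/H tuples are inferences; analyses that hinge on those two groups
  should treat their membership as provisional (the `inferred` flag is
  carried through all outputs).
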