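# stressclust

Categorical temporal clustering of stress-response gene expression, with
pathway and promoter-motif enrichment that nominates upstream regulators.

## The problem

Acute endoplasmic-reticulum (ER) stress in the liver reshapes the
transcriptome: canonical unfolded-protein-response (UPR) targets are induced,
but a large fraction of regulated genes — notably lipid-metabolism genes —
are *suppressed*, by mechanisms that no canonical UPR activator explains.
A "bottom-up" way to find the hidden regulators is to profile expression in
a factorial design — wild-type (WT) vs. an ER-stress-sensor knockout (KO),
vehicle vs. stressor (tunicamycin, TM), early (8 h) vs. late (34 h) — and
group genes purely by the *category* of their response, then ask which
pathways and which transcription-factor binding sites are over-represented
in each group.

`stressclust` implements that pipeline end to end for analysts working with
such factorial designs, and ships a synthetic-data generator that plants
every layer of structure (profiles, pathway memberships, promoter motifs) as
machine-readable ground truth, so the whole chain is testable by recovery.

## The method

1. **Three-state calls.** For each gene and each of four canonical
   comparisons — c1: WT-TM/WT-vehicle at 8 h, c2: KO-TM/WT-TM at 8 h,
   c3 and c4: the same at 34 h — compute the log2 ratio of linear replicate
   means and a pooled two-tailed Student *t*-test, then call
   `up` if log2FC ≥ log2(1.5) ≈ 0.58 and *p* < 0.05, `down` for the mirror
   image, else `unchanged`.
2. **Profile clustering.** The ordered 4-tuple of calls is a gene's
   expression profile — one of 3⁴ = 81. Genes with c4 = `unchanged` (no
   late genotype difference) are filtered out, leaving 3³·2 = 54 admissible
   profiles; the most populated carry the letter names A–I plus the profile
   expected of direct ATF6 targets. Multiple probesets per gene collapse to
   the modal profile with deterministic tie-breaks.
3. **Pathway enrichment.** Per group, exact hypergeometric
   over-representation P(X ≥ k) against the array universe with
   Benjamini–Hochberg FDR at 5%; reports list the top seven terms reordered
   by gene hits.
4. **Motif enrichment.** Promoter windows of ±2000 bp around each TSS are
   scanned on both strands with JASPAR-format PWMs (relative log-odds score
   ≥ 0.85). Per factor, a binomial background-rate Z-score on site counts
   (with continuity correction) and a one-tailed Fisher exact test on
   genes-with-hits; factors pass at Z > 10 and Fisher *p* < 0.01. Passing
   regulator→target edges export as a TSV edge list.
5. **Validation statistics.** ChIP-qPCR percent input
   (100·2^(adjusted input Ct − IP Ct)), one-way ANOVA, and group *t*-tests.

## Worked example

```python
import stressclust as sc

cfg = sc.GeneratorConfig(seed=1)          # 600 genes, 10 groups x 30, n=3
design = sc.generate_design(cfg)          # 24 samples, 8 condition groups
matrix, truth = sc.generate_expression(cfg, design)

calls = sc.call_comparisons(matrix, design)
table, counts = sc.label_groups(sc.assign_profiles(calls))
print(counts.head(4))
```

```
tally
A    30
B    30
C    30
D    30
Name: n_genes, dtype: int64
```

All 30 genes planted in each group recover their label. Scanning the
generated promoters and testing the ATF6-profile group:

```python
pwms = sc.default_pwms()
promoters, tss = sc.generate_promoters(cfg, truth, pwms)
scan = sc.scan_promoters(pwms, promoters, dict(zip(tss["name"], tss["start"])))
groups = truth.profiles["group"]
res = sc.single_site_analysis(scan, set(groups[groups == "ATF6"].index),
                              sorted(promoters))
print(res.loc[res["passes"], ["factor", "x", "z", "fisher_p"]])
```

```
     factor   x          z      fisher_p
4  NFYA_SYN  54  26.946403  7.147291e-33
```

The factor planted only in ATF6-group promoters is the sole significant hit
(Z ≈ 27 against the Z > 10 cutoff); the factor planted in the downregulated
groups B, D and F passes in exactly those three groups. The same run is
available as a shell pipeline: `stressclust run --config run.yaml` executes
generate → calls → cluster → enrich → motifs and writes a manifest with
per-stage checksums.

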