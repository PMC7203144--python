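# erdomains

Comparative immuno-isolation proteomics of endoplasmic-reticulum (ER)
domains.

The ER is organised into two morphologically distinct domains: ribosome-
studded **sheets** (marker: Climp63/CKAP4) and high-curvature **tubules**
(markers: DP1/REEP5, reticulons). Membrane proteins partition between these
domains, and disease mutations can shift that partitioning — the ALS-linked
VAPB-P56S mutation, for example, delocalises the ER-organelle tethering
protein VAPB from tubules. `erdomains` implements the full desk-side
analysis for studying this by affinity-purification mass spectrometry
(AP-MS): starting from label-free-quantification (LFQ) protein abundance
tables of immunoprecipitated (IP) ER membranes, it

1. **normalizes** IP samples (median centering on the control-detected
   background and/or bait-protein scaling) and **excludes** non-specific
   (control-IP-positive) and low-abundance proteins;
2. computes per-antibody **log2 fold changes** between two baits and calls
   **reference proteomes** — proteins enriched toward one bait
   (|log2FC| ≥ τ, default τ = 1) in *every* antibody set of *every*
   biological replicate;
3. **scores the domain property** of a query IP proteome by grouping its
   averaged log2FCs by reference class and testing class differences with
   one-way ANOVA followed by Tukey's HSD;
4. calls the **mutant-reduced set** (mean log2FC mutant/wt < −0.5, strict)
   and scans it for **FFAT-like motifs** ("two phenylalanines in an acidic
   tract", the short linear motif bound by the VAP MSP domain) with
   position-penalty scoring — a 13-mer window (6-residue acidic tract +
   E-F-F-D-A-x-E core) scores the sum of per-position substitution
   penalties, lower is better, and a total < 3 is a *strong* motif;
5. analyses **proximity ligation assay (PLA)** per-cell intensity tables:
   median-normalize the PLA and EGFP channels, gate cells on EGFP
   expression (> 5000, strict), form per-cell PLA/EGFP ratios, and compare
   conditions with Welch's two-tailed *t* test (an F test for equal
   variances is always reported alongside).

Because raw AP-MS runs and microscopy images live upstream of this package,
it ships a first-class **synthetic-data generator** that emulates the whole
study design with planted ground truth — bait-dependent capture, per-sample
antibody effects, multiplicative lognormal LFQ noise, rank-based
low-abundance dropout, planted sequence motifs, and two-condition per-cell
intensity tables with unequal variances — so every stage is testable by
parameter recovery.

## Worked example

```python
import erdomains as ed

# 1) simulate a two-bait x two-antibody x two-replicate IP experiment
cfg = ed.sheet_tubule_config(seed=1)          # 200 sheet, 50 tubule, 1250 background
matrix, truth = ed.simulate_ip_experiment(cfg)

# 2) normalize, fold changes, reference proteomes at tau = 1
spec = ed.NormalizationSpec()
fc = ed.fold_changes(ed.normalize(matrix, spec), "Climp63", "DP1")
sheet = ed.call_enriched(fc, tau=1.0, side="numerator", name="sheet")
tubule = ed.call_enriched(fc, tau=1.0, side="denominator", name="tubule")
print(f"sheet reference:  {len(sheet.members)} proteins")
print(f"tubule reference: {len(tubule.members)} proteins")

# 3) mutant-vs-wt experiment with the tubule capture halved
mcfg = ed.vapb_config(seed=2, tubule_reduction=0.5)
mmatrix, _ = ed.simulate_ip_experiment(mcfg)
mfc = ed.fold_changes(ed.normalize(mmatrix, spec), "VAPB-P56S", "VAPB-wt")
score = ed.class_shift_test(mfc, [sheet, tubule])
for name, cs in score.per_class.items():
    print(f"{name:7s} n={cs.n:4d} mean log2FC = {cs.mean_log2fc:+.3f}")

# 4) reduced set and PLA statistics
reduced = ed.reduced_set(mfc, cutoff=-0.5)
cells = ed.simulate_pla(150, effect=0.55, var_ratio=2.0, seed=3)
pla = ed.pla_ratio_test(cells, egfp_gate=5000)
print(f"PLA effect (mutant/wt) = {pla.effect:.3f}, Welch p = {pla.welch_p:.2e}")
```

prints

```
sheet reference:  188 proteins
tubule reference: 48 proteins
sheet   n= 186 mean log2FC = +0.006
tubule  n=  47 mean log2FC = -0.992
PLA effect (mutant/wt) = 0.544, Welch p = 5.43e-23
```

The sheet class is unshifted (mean ≈ 0), the tubule class sits at the
planted log2(0.5) ≈ −1, and the PLA test recovers the planted 0.55 ratio
reduction. The Tukey sheet–tubule contrast is significant
(p_adj ≈ 6 × 10⁻¹⁴).

## Command line

```sh
erdomains simulate  --seed 3 --outdir data/          # synthetic inputs + truth
erdomains enrich    --abundance data/abundance.tsv --meta data/samples.tsv \
                    --numerator Climp63 --denominator DP1 --outdir enriched/
erdomains ffat-scan --fasta data/proteome.fasta --out hits.tsv
erdomains pla-test  --cells data/pla_cells.tsv --out pla.tsv
erdomains run-all   --seed 3 --outdir results/       # every stage end to end
```

`run-all` writes every intermediate table plus a `manifest.json` recording
all thresholds; reruns with the same config and seed are byte-identical.

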