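# Methods

This note documents the models, defaults and numerical choices behind
`erdomains`, in the order the pipeline runs.

## Generative model of the IP experiment

`simulate_ip_experiment` draws, for protein *i* and sample *s*,

```
abundance[i, s] = base_i · capture[bait_s][class_i] · a_s · 2^ε,   ε ~ N(0, noise_sd²)
```

with `base_i = 2^N(20, 3²)` (an LFQ-like scale spanning roughly four
decades), a per-sample multiplicative antibody/IP-efficiency effect
`a_s = 2^N(0, antibody_effect_sd²)`, and multiplicative lognormal
measurement noise. Multiplicative-lognormal is the standard error model for
LFQ intensities and gives closed-form expectations: with noise, antibody
effects and dropout off, the log2 fold change of a class equals log2 of its
capture ratio *bit-exactly* whenever the capture multipliers are powers of
two (4:1 capture → log2FC = 2.0 exactly), which anchors the closed-form
tests.

Design defaults mirror the real study's scale: two baits × two antibodies ×
two biological replicates; 200 sheet-specific, 50 tubule-specific and 1250
background proteins; reciprocal 4:1 sheet/tubule capture for the
Climp63/DP1 pair; equal (2:2) intermediate capture for the VAPB wild-type/
mutant pair, with the mutant's tubule capture multiplied by
`tubule_reduction`. Tag-only control IPs capture only background proteins.
Each bait's own tagged protein is planted at class-independent high
abundance (2^26) so bait normalization can be exercised.

Parameter defaults and rationale:

| parameter           | default | meaning / why |
|---------------------|---------|---------------|
| `noise_sd`          | 0.3     | log2-scale residual sd; a ~20–25% CV, typical for protein-level LFQ |
| `antibody_effect_sd`| 0.2     | log2-scale per-sample IP-efficiency spread |
| `dropout_quantile`  | 0.02    | lowest fraction of positive *expected* values set missing |
| `tubule_reduction`  | 1.0     | capture multiplier on the mutant bait's tubule class |

Dropout is tied to expected-abundance rank (the lowest fraction goes
missing) rather than being random, because it models the detection floor
that motivates the pipeline's low-abundance exclusion. The default is a
few per cent because it represents *protein-group-level* missingness of
aggregated LFQ values: the enrichment caller treats any missing fold change
as a failed threshold, so each planted protein needs a complete measurement
in all four antibody × replicate sets, and per-cell dropout rates much
above this would make the stated ≥0.9 recovery sensitivity unreachable for
reasons unrelated to the caller. Peptide-level missingness in raw LFQ data
is considerably higher; this generator works at the protein-group level
throughout.

What the generator does *not* emulate: peptide-to-protein roll-up,
intensity-dependent (heteroskedastic) noise, ratio compression, shared
peptides between protein groups, and correlated co-complex abundances.
Passing the recovery tests therefore demonstrates that the estimators are
correct under a clean multiplicative error model, not that real AP-MS data
will reach the same sensitivity.

## Normalization

Two switchable steps, applied in the configured order (default
median → bait, each step running only when enabled/applicable):

* **Median centering** scales each sample so its median non-missing
  abundance equals the grand median (median of per-sample medians). By
  default the median is computed over the proteins *detected in the
  tag-only control IPs* (`median_scope="auto"`): control-detected proteins
  are non-specific background whose capture is bait-independent by design,
  making them an invariant anchor set. Using all proteins
  (`median_scope="all"`) is supported but composition-biased here: a
  sizable specifically-captured class (e.g. 200 sheet proteins at 4×)
  shifts one bait's bulk median and biases every fold change by ~0.15 log2
  units in the default design.
* **Bait scaling** rescales each non-control sample so its captured
  bait-protein abundance equals the across-sample mean bait abundance,
  removing IP-efficiency differences. It is exact on noise-free data but
  propagates the bait protein's own measurement error into every fold
  change (two extra noise terms of `noise_sd` per comparison), so the
  default pipeline relies on the median step and leaves bait scaling
  opt-in (`bait_normalize`). Both the steps applied and their order are
  recorded in the matrix log and the run manifest.

## Exclusion

A protein is **non-specific** if, in any IP/matched-control comparison
(matched on tag + antibody, same replicate preferred), the control carries
at least `min_control_fraction` (default 0.5) of the IP abundance — or is
present in the control while absent from the IP. A presence/absence rule
alone is too brittle under LFQ noise, hence the fractional threshold. A
protein is **low-abundance** if its best IP measurement falls below the
`low_abundance_quantile` (default 0.05) of the pooled IP abundance
distribution. Whether the underlying instrument threshold is absolute or
relative is unknowable from our inputs; a pooled quantile is the
scale-free choice.

## Fold changes and enrichment calls

Per antibody set and replicate, `log2(numerator / denominator)` of the
normalized abundances. Zeros and missing values yield a missing fold
change — never imputed — and a missing fold change fails every threshold.
Fold changes are computed as `log2(a/b)` rather than `log2(a) − log2(b)`:
the ratio form keeps exact-power-of-two ratios bit-exact (the closed-form
anchor), at the cost of antisymmetry holding only to the last ulp rather
than bitwise.

`call_enriched` makes a protein a reference-proteome member iff its signed
log2FC meets the threshold (≥ τ numerator side, ≤ −τ denominator side) in
**every antibody set of every replicate** — full concordance, the strictest
reading of replicate intersection; it is monotone in τ by construction.
τ defaults to 1 (two-fold): the scatter of known domain markers separates
well beyond two-fold, and the recovery tests show τ = 1 gives ≥0.9
sensitivity and precision under the default noise.

`reduced_set` averages each protein's fold changes across antibody sets
(and replicates) and applies a strict `< cutoff` (default −0.5)
inequality; a protein sitting exactly at the cutoff is *not* reduced.

`select_top_n` ranks by mean normalized abundance in the bait's samples,
breaks ties lexicographically by accession, takes the top *n*, then removes
the subtraction set — subtraction happens *after* ranking, so the returned
list can be shorter than *n*.

## Domain scoring

"Averaged log2FCs" means: average across antibody sets per protein first,
then treat proteins as the observations. Groups are the reference-proteome
classes (plus optional user-supplied annotation sets, which may overlap);
classes with fewer than two covered proteins are dropped with a warning,
and at least two classes must remain. Group differences are tested with
one-way ANOVA and Tukey's HSD at family-wise α = 0.05 (the conventional
level). The four-group variant (wt/mut × sheet/tubule in one family) is
available via `class_shift_test(..., fc_wt=...)`. Under the no-effect
simulation the ANOVA p-value is uniform (KS-checked over hundreds of
replicates), and adding a constant to every fold change moves class means
without touching any contrast.

## FFAT-like motif scanning

A 13-residue window slides over positions 1..L−12 (1-based, inclusive);
positions 1–6 are the acidic tract, 7–13 the core (consensus E-F-F-D-A-x-E).
The window score is the sum of per-position penalties from the matrix file
`src/erdomains/data/ffat_position_penalties.tsv` — the single source of
truth; alternative matrices in the same layout are accepted for
sensitivity analysis. The packaged matrix implements the Murphy–Levine
penalty-scoring scheme: acidity penalties on the tract (D/E = 0,
phosphorylatable S/T at half penalty, basic residues extra) with position
weights rising toward the core and summing to 3.0 for a fully non-acidic
neutral tract; core substitution penalties growing with biochemical
distance from the consensus, the second phenylalanine being the least
substitutable; consensus residues score 0, so the canonical motif in an
ideal acidic context scores exactly 0. All penalty values are exact binary
fractions, so boundary comparisons (a window at exactly 3.0) are not
clouded by rounding.

Conventions: total < cutoff (default 3.0, strict) is a *strong* motif; X
receives each position's maximum penalty (worst case); other ambiguity
codes are rejected at read time; hits report both the 13-mer start and the
core start; default reporting is the single best (minimum) window per
protein, matching one-motif-per-protein hit tables, with
`all_below_cutoff` available. `scan_reduced_set` first keeps the longest
isoform per gene (ties: lexicographically smallest sequence id). The
scanner is vectorized; the test suite checks it window-for-window against
an independent brute-force rescorer that reads the matrix file directly.

## PLA statistics

Both channels are divided by their across-all-cells medians; cells are
gated on EGFP strictly greater than the threshold; the per-cell ratio is
normalized PLA / normalized EGFP; the effect is the mutant/wt quotient of
condition mean ratios. The Methods-style "gate at 5000" is meaningful only
on raw intensities, so gating is applied to the raw EGFP channel by
default, with `gate_on="normalized"` available (use a gate near 1 in that
mode); the gate mode and threshold are always reported. The F test for
equal variances is computed and reported but never used to choose the
test: Welch's two-tailed *t* test is always the inference, avoiding the
conditional-testing pitfall. Rescaling both channels by a common constant
cancels in every ratio and in the effect; with power-of-two constants the
cancellation is IEEE-exact, which is how the bit-identity test is posed.
`pooled_pla_summary` combines ≥2 experiments with equal weights (mean and
SD of per-experiment effects).

The PLA generator plants a true mean-ratio effect with lognormal per-cell
ratios (wt mean ratio 0.5, CV 0.3) and EGFP lognormal around a median of
20 000 — well above the 5000 gate so gating removes only a small tail —
and scales the mutant ratio variance by `var_ratio` to reproduce the
unequal-variance situation that motivates Welch's test.

## Determinism and problem sizes

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; `run_full` writes no timestamps, so identical
config + seed gives byte-identical result directories. The test suite and
`scripts/acceptance.py` use desk-scale problem sizes — 1500-protein
simulations, 10–20 seeds for recovery averages, 300–500 replicates for
null calibration, 50–100 PLA experiments — chosen so the whole suite runs
in a few minutes on one CPU while keeping Monte-Carlo error well inside
the asserted margins.

## Known limitations

* The enrichment caller has no error model per protein (no moderated
  variance, no multiple-testing control) — by design, it reproduces a
  threshold-based calling scheme; treat member lists as operational, not
  inferential.
* Reference proteomes and query comparisons must currently come from the
  same accession namespace; no ortholog/ID mapping is provided.
* The FFAT matrix encodes the published scheme's structure with
  reconstructed penalty values; for work that depends on exact published
  scores, drop a transcribed matrix file in via `--matrix` / `load_matrix`.
* PLA analysis starts at the per-cell intensity table; segmentation,
  background subtraction and spot counting are upstream and out of scope.
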