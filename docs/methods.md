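# Methods

This note documents the models, conventions and numerical choices behind
`solscore`, and what the synthetic testbed does and does not establish.

## Categorical model of expression outcomes

Every record carries an outcome (expressed flag, soluble yield in mg per
ml of extract, full-length flag) and is scored into exactly one category:

* **A** — expressed, full length, soluble yield **strictly above** the
  threshold (default 0.1 mg/ml, the practical detection limit against the
  background of endogenous extract proteins on a stained gel);
* **C** — expressed at full length but at or below the threshold in the
  soluble fraction;
* **N** — not expressed, or expressed below the expected molecular size
  (truncated chains cannot attain native structure, so they are scored
  with the non-expressed class).

A yield exactly equal to the threshold is scored C: the soluble class is
defined by *more than* threshold, and the boundary is tested explicitly.
Mixed soluble/insoluble expression is encoded solely through the reported
soluble yield against the threshold — no separate "both fractions" state
exists, which keeps the three categories mutually exclusive and
exhaustive.  Replicate reconciliation is upstream of this package: one
outcome per id.

Sequences are restricted to the 20 standard residues.  Ambiguity codes
(B, Z, X), U, stops and gaps are rejected rather than silently mapped,
because every feature scale below is undefined for them; a
`--drop-invalid` CLI flag skips such records with a logged warning.

## Physicochemical features

* **Molecular weight**: sum of average (not monoisotopic) Expasy residue
  masses plus one water (18.0153 Da) — the ProtParam convention.
* **Net charge** at pH: Henderson–Hasselbalch sum over both termini and
  the C, D, E, H, K, R, Y side chains,
  `+Σ 1/(1+10^(pH−pKa))` for bases, `−Σ 1/(1+10^(pKa−pH))` for acids.
  The default pKa set is the EMBOSS one (N-term 8.6, C-term 3.6, C 8.5,
  D 3.9, E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1); the Bjellqvist set used
  by ProtParam itself can be supplied through `PhyschemConfig`, which
  reconciles both conventions.
* **pI**: the unique zero of the strictly decreasing titration curve,
  found by bisection on [0, 14] until |charge| < 1e-4 (at most 200
  iterations).  On sequences with few ionizable groups the curve is flat
  near its zero, so the charge tolerance corresponds to roughly ±0.01 pH;
  tests compare against a 0.001-pH grid-scan oracle at that tolerance.
* **GRAVY**: arithmetic mean of Kyte–Doolittle values.  The hydropathy
  scale is configurable; Kyte–Doolittle is the documented default.
* **Charged-residue features**: `n_positive = K + R` and
  `n_negative = D + E` (histidine titrates but is excluded from the count
  features, the usual convention at pH 7).  Both counts are also exported
  as per-length densities, and the correlation analysis uses densities so
  that sequence length does not confound them.

## Motif and PTM-site scanning

A PROSITE-syntax pattern engine (literals, `x`, `[..]`, `{..}`, `(n)`,
`(n,m)`, `<`/`>` whole-pattern anchors, `-` separators) with a
backtracking matcher.  Semantics: every start position is scanned
(overlapping matches are all reported); at each start the
leftmost-shortest expansion of variable repeats is reported; coordinates
are 1-based inclusive.  Two documented divergences from PS_SCAN: the
skip-flag convention for high-probability patterns is not emulated, and
anchors inside bracket expressions (`[G>]`) are rejected.  The engine is
validated against an independent regular-expression translation oracle
on random sequences.

The bundled catalogue holds the classical consensus patterns for the PTM
classes of interest (N-glycosylation, PKA/PKC/CK2 phosphosites,
N-myristoylation, amidation, Asx hydroxylation in its EGF-domain
context, a simplified acidic-context sulfation rule, and the C-terminal
CaaX prenylation box) in an editable two-column-plus-kind text file; each
pattern declares whether it enters the analysis as a presence flag
(binary) or a site count (discrete).  Users are expected to extend it.

## Structural features

* **PEST regions**: candidate stretches between positively charged
  flanks (K/R/H, or the sequence ends) of length ≥ 12 containing ≥ 1 P,
  ≥ 1 of D/E and ≥ 1 of S/T, scored
  `0.55 · mole%(DEPST) − 0.5 · mean(10·KD + 45)` — the classical
  epestfind-style combination of DEPST enrichment and hydropathy
  rescaled onto a 0–90 scale.  Scores above +5 count as "interesting"
  (configurable); all candidates are returned with their scores.
* **Coiled coils**: Lupas sliding-window method, window 28, all 7 heptad
  registers; a residue's score is the maximum geometric mean of
  positional propensities over windows covering it.  The propensity table
  is a bundled editable TSV adapted from the classical heptad frequency
  statistics, with zero entries floored at 0.01 so geometric means stay
  positive; the two-Gaussian probability conversion of the original tool
  is intentionally omitted — the raw score with a threshold (default 1.3)
  keeps the feature deterministic and auditable.  Sequences shorter than
  one window score zero.
* **Transmembrane** (`baseline:n_tm`) and **disorder**
  (`baseline:disorder_fraction`) are transparent stand-ins, not
  re-implementations of trained predictors: maximal 19-residue windows of
  mean Kyte–Doolittle hydropathy ≥ 1.6 (merged when overlapping), and the
  fraction of positions whose 21-residue running mean of the TOP-IDP
  composition scale exceeds 0.1.  Their names carry the `baseline:`
  prefix in every output so they cannot be mistaken for external-tool
  results.  Predictions from trained tools enter through the adapter TSV
  (`id, feature, kind, value`); ids without a value for a feature are
  declared missing, logged, and excluded from that feature's correlation.

## Correlation analysis and statistics

Yes/no features: per category k ∈ {A, C, N}, the 2×2 table
(present∧k, present∧¬k, absent∧k, absent∧¬k) is tested with Fisher's
exact test; the association direction is the sign of (odds ratio − 1).
All three per-category tables share the dataset's grand total.  Constant
features are ND.

Discrete and continuous features are binned over their full observed
range: one bin per value with adjacent sparse values merged until every
bin holds ≥ `min_bin` (default 20) records for discrete features;
quantile bins (default 10, ties collapsed) for continuous ones.  Per bin,
the A/C/N percentages (always a partition summing to 100) and the record
count (the dataset's distribution over bins) are computed.  Pearson's r
is then taken between the per-bin category percentage and the bin
representative (the value itself for discrete bins, the within-bin mean
for continuous bins — bin indices are *not* used), with n = number of
bins and a one-tailed p in the direction of the observed sign.  Fewer
than 3 usable bins gives ND.

Curve smoothing (centred moving average, default window 3, edge-shrunk)
is a presentation aid; by default correlation runs on the raw
percentages, and a config switch (`correlate_smoothed`) exists for
mimicking smoothed-graph analyses.  A moving average was chosen over a
spline because it is order-independent and parameter-light; since the
same weights apply to all three curves it preserves the percentage
partition.

Sign calls: `+` / `−` for a significant overall correlation; `±` when
the lower-half and upper-half correlations of the profile (middle bin
shared when the bin count is odd; each half needs ≥ 3 bins) are
individually significant with opposite signs.  The `±` rule takes
precedence over the overall call, so a V-shaped profile whose overall r
happens to reach significance is still reported as non-monotone.  `ND`
covers everything else — not significant, undefined (zero variance), or
untestable.  This operationalisation of `±`/`ND` is the package's own
reproducible rule; qualitative summaries of this kind have no single
established definition.

No multiple-testing correction is applied by default (per-feature
α = 0.05); Benjamini–Hochberg adjusted p-values are always reported
alongside, and `use_bh` makes them drive significance.

### Exact statistics

Implemented from scratch so the analysis does not depend on a statistics
library: Fisher's two-sided p follows the minimum-likelihood rule (the
convention of the standard 2×2 calculators), computed with exact integer
hypergeometric weights (rational arithmetic) for grand totals ≤ 500 and
in log space (log-gamma factorials, relative tie tolerance 1e-7) above;
one-sided alternatives are exposed.  The t tail behind the one-tailed
correlation p uses a continued-fraction regularised incomplete beta.
Tests cross-check all of these against exhaustive enumeration and scipy.
The direction of the one-tailed test is taken from the observed sign of
r, and this convention is part of the sign-call definition above.

## Synthetic datasets

The generator emulates the statistical shape of a large uniform-condition
cell-free screen at configurable scale.  Defaults (the package's study
conditions): n = 3000 records, lengths uniform on 50–300 residues,
i.i.d. residues at vertebrate background frequencies, base rates
A = 0.257 (the soluble rate observed in large screens), with the
remainder split near-evenly C = 0.370 / N = 0.373 since no reference
value for that split exists.  Categories follow a multinomial logit:
log-odds = log(base rate) plus, for each planted effect, β·z(feature)
with z standardised over the batch; β is therefore in units of log-odds
per feature SD, and β = 0 recovers the base rates.  A logit model (rather
than hard thresholds) yields the smooth monotone percentage curves the
profile analysis assumes.  Motif plants overwrite a minimal pattern
instance into a configurable fraction of sequences, at the terminus for
anchored patterns.

Outcome records are back-filled per category — A: yield = threshold +
Exp(0.4 mg/ml); C: yield ~ U(0, threshold); N: non-expressed (80%) or
truncated (20%) — so the categorical assessment path is exercised end to
end rather than bypassed.  Determinism: one seed sequence per generate
call, split per record; identical (config, seed) reproduces the dataset
bit for bit.

What the generator does **not** emulate: real domain architecture,
homology structure, codon/expression covariates, correlated features
beyond those induced by composition, or measurement noise in yields.
Passing recovery tests therefore shows that the analysis machinery
detects monotone effects of the planted size under idealised sampling —
not that any particular biological association holds.

## Validation study sizes

The validation suite and `scripts/acceptance.py` use: exhaustive Fisher
sweep over all 2×2 tables with grand total ≤ 30 (46,375 tables, exact to
1e-12); pI checks on 200 random sequences against a 0.001-pH grid scan;
motif-engine equivalence on 1,000 random 300-mers across the whole
catalogue; null calibration of the binary association test over 500
replicates of n = 2000 (the per-category false-positive rate must sit in
the 99% binomial envelope of α = 0.05); planted-sign recovery over 20
seeded n = 3000 runs (β = 1 on a continuous and a planted binary
feature, ≥ 95% required); and a byte-identity rerun of the CLI pipeline.
In the null-calibration study categories are drawn directly from the
generator's category model (with no planted effects the sequence content
does not influence the category draw), which keeps the 500-replicate
study cheap without changing what is tested.

## Known limitations

* The TM/disorder baselines are crude relative to trained predictors;
  real analyses should supply external predictions via the adapter.
* The bundled motif catalogue is a small classical subset of PROSITE;
  pattern-based site prediction over-calls heavily on random sequence,
  which the per-category contingency design tolerates but does not fix.
* Fisher p-values for grand totals above 500 carry the 1e-7 tie
  tolerance of the log-space path.
* The `±` and `ND` calls are operational definitions; other reasonable
  definitions (e.g. quadratic-term tests) would classify borderline
  profiles differently.
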