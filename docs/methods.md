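# Methods

## Scope and data flow

`pipesim` simulates a two-class label-free LC-MS experiment end to end:

1. **Proteome** (`proteome`) — read a FASTA file or generate a synthetic
   proteome; digest with the trypsin rule (cleave C-terminal to K/R except
   before P); annotate peptides with monoisotopic mass, predicted retention
   time and parent-protein sets.
2. **Ground truth** (`abundance_model`) — Gamma protein means, fold-changed
   markers, block-correlated multivariate Gaussian sample variation.
3. **Signal** (`signal_model`) — peptide concentration roll-down, efficiency
   and instrument response, saturation, quadratic-variance Gaussian noise.
4. **Detection** (`detection`) — SNR- and overlap-dependent MS1 true positive
   rate, per-species MS2 identifiability with replicates, AND-linking.
5. **Roll-up** (`rollup`) — unique/missing-rate/correlation filters,
   averaging, quantification error and missing-value rates.
6. **Analysis** (`analysis`) — per-protein t-tests, marker recovery,
   top-|t| feature selection, 3-NN and ridge-LDA classification on observed
   versus uncorrupted data, and the binomial quantification bound.
7. **Experiments** (`experiments`) — seeded single runs and replicated
   parameter sweeps with median/mean/sd aggregation.

The simulator deliberately stays above the physics: no isotope envelopes,
charge states, raw spectra or database-search scores are produced. What it
preserves is the *statistical* structure of the data path — where signal is
lost, where variance enters, and how those losses propagate to
quantification, differential expression and classification.

## Parameters that matter

| Parameter | Default | Meaning |
|---|---|---|
| t, θ | 2, 1000 | Gamma shape/scale of control protein means (dimensionless concentration units) |
| M | 50 | samples per class |
| markers / background | 20 / 500 | proteins with / without a class fold change |
| a_l | Unif(1.5, 2) | fold-change magnitude; direction by fair coin |
| ρ, D | 0.6, 2 | within-block correlation and block size |
| φ | 0.1 | coefficient of variation: per-protein sd = φ·η |
| e_i | Unif(0.1, 1) | per-peptide efficiency (LC transmission × ionization) |
| κ | 5 | instrument response factor (signal per unit concentration) |
| sat | ∞ | expected-abundance ceiling; linear dynamic range ≈ sat/(e·κ) |
| α, β | 0.03, 3.6 | noise variance αμ² + βμ |
| k, p, b | 0.0016, 2, 0 | MS1 TPR curve k·SNR^p + b |
| resolution | 50 000 | mass resolving power in the overlap criterion |
| p_i | Beta(2, 8) | MS2 identifiability per peptide species (mean 0.2) |
| r | 1 | MS2 replicates; success prob. 1 − (1 − p_i)^r |

Concentration units and κ are treated as dimensionless scale factors; only
their ratios to `sat` and to the noise coefficients matter.

## Design choices where the design was open

- **SNR form.** SNR is defined as E[v]²/Var(v), which with the quadratic
  noise model gives μ²/(αμ² + βμ) = μ/(αμ + β): zero at zero signal,
  monotone increasing, saturating at 1/α. This is the only form consistent
  with both the definition and the requirement that stronger signals be
  easier to detect.
- **Interpretation of the noise law** as a *variance* (not sd): the SNR
  expression above requires Var(v) = αμ² + βμ.
- **σ as standard deviation.** The per-protein spread is σ_l = φ·η_l, so φ
  is literally a coefficient of variation. φ is a single scalar for all
  proteins (per-protein CVs are supported by the model but add a confounder
  without a principled default).
- **Marker placement.** Markers sit at the start of each correlation block
  (rows 0, D, 2D, ...), so every marker's block partners are background
  proteins. This exposes marker-background correlation to the classifier,
  the more informative layout; co-blocking markers with markers would make
  their signals partially redundant.
- **Clamping.** Negative Gaussian draws (concentrations, ion counts) are
  clamped to zero; at φ = 0.1 the clamping probability is ≈ Φ(−10) per cell
  and empirically < 1% even at stressed settings.
- **Saturation before noise.** The ceiling applies to the expected
  abundance μ; noise is added afterwards, so saturated cells still vary.
- **Overlap criterion.** Two peptides clash when their relative mass gap is
  below 1/resolution — computed against the smaller mass, making the test
  symmetric — and their RT gap is below 0.5% of the gradient. A peptide's
  clash group counts itself, so the overlap-sensitive attenuation 1/count
  is 1 for isolated peptides. Overlap is computed once per catalog: masses
  and (deterministic) RTs do not vary by sample.
- **Retention-time stand-in.** RT prediction is a deterministic logistic of
  the mean Kyte-Doolittle hydropathy mapped onto (0, n_scans). Only
  *relative* RT proximity enters the model (the overlap criterion), so any
  monotone deterministic predictor yields the same mechanism.
- **Identifiability stand-in.** Trained spectral-identifiability predictors
  need external weights; the default is a seeded per-species Beta(2, 8)
  draw (mean 0.2, matching typical single-run identification rates), with a
  deterministic sequence-based logistic alternative (`logistic`) and an
  idealised `perfect` model for noiseless checks. MS2 trials are re-drawn
  per sample: under-sampling makes precursor selection poorly reproducible
  across runs.
- **Stage-3 correlation rule.** A peptide passes when its *best* sibling
  correlation exceeds the threshold (robust to one bad sibling), computed
  over pairwise-complete samples with at least 3 common observations; a
  protein reduced to a single peptide has no sibling and cannot qualify.
- **qerr includes unquantified proteins** (per-entry relative error 1).
  Restricting to quantified proteins would reward dropping hard proteins.
  Cells with a true concentration of exactly zero (clamped draws) are
  excluded with a warning, since relative error is undefined there.
- **Test-set construction.** Classifiers are validated on freshly drawn
  samples from the same generative model, pushed through the *same*
  pipeline realisation — identical efficiencies, identifiabilities and
  overlap structure, fresh noise/detection draws — and rolled up with the
  training-derived survivor sets, so train and test live in the same
  feature space. Original-data classifiers use the uncorrupted
  concentrations on both sides.
- **LDA/KNN conventions.** LDA uses the pooled covariance with a 10⁻⁶ ridge
  and equal priors; KNN uses brute-force Euclidean 3-NN. Feature ties are
  broken toward the smaller protein index.
- **Multiple testing.** Marker detection uses the raw per-protein level
  0.05 (a Benjamini-Hochberg option exists but is off by default), matching
  common small-sample marker-screen practice.
- **Numerical exactness of the roll-up mean.** Protein estimates use a
  shifted mean (first observed value plus mean deviation), which avoids
  cancellation and returns the exact common value when all surviving
  peptides agree — this is what makes the distortion-free pipeline
  reproduce the truth with qerr identically zero.

## Randomness

Every stochastic stage draws from its own named substream derived from
`(seed, stage name)` via CRC-32-keyed `SeedSequence`s, so adding draws in
one stage never perturbs another. Composed stages (train vs test noise,
subsampling, efficiencies, ...) receive tagged sub-seeds of the run seed.
Runs are bit-reproducible for a given seed, and a committed golden
snapshot (`tests/data/golden_run.json`) guards the whole pipeline against
silent numeric drift.

## The synthetic proteome, and what passing tests do not show

The generator draws i.i.d. residues at Swiss-Prot background frequencies
with normal lengths (mean 350, sd 100, truncated at 50) — chosen so that
tryptic digestion at 0 missed cleavages with length bounds 6–40 yields
roughly 20 peptides per protein, the typical ratio for human proteins.
Digestion defaults (0 missed cleavages, lengths 6–40) are standard
search-engine settings.

Real proteomes differ in ways the generator does not emulate: homologous
sequence families (shared peptides are much rarer in i.i.d. sequences, so
the uniqueness filter bites less here), composition biases, modified
residues, and sequence-correlated detectability. Trend results (how
performance moves with efficiency, κ, noise, resolution, replicates, M)
transfer; absolute index values do not, and are additionally sensitive to
the identifiability stand-in.

## Problem sizes used by the tests

Unit tests run on a hand-checkable 5-protein toy proteome whose tryptic
products are enumerable by construction. The sweep behaviours are asserted
at reduced scale — 100 background + 20 marker proteins subsampled from a
300-protein synthetic proteome, 10 replicate runs per grid value, 500 test
samples per class — sizes chosen so a full-suite run stays in the
low minutes while every mechanism (filters, overlap, saturation,
replication) remains active. The mass-resolution comparison runs at a
resolving power of 100: with ~2 500 peptides the clash density at that
setting emulates what a far more complex sample experiences at realistic
resolutions.

## Known limitations

- No false-positive features are generated; the AND-link models FP
  *suppression* only.
- Charge states, isotope envelopes and raw spectra are out of scope.
- Two classes only; the generative model extends to more, but the
  evaluation (t-test, binary classifiers) is written for two.
- Plain averaging roll-up; median-polish or pairwise-ratio schemes are not
  implemented.
- The RT and identifiability stand-ins are deterministic simplifications;
  conclusions that hinge on *which specific* peptides co-elute or identify
  should not be drawn from this simulator.
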