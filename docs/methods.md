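# Methods

`proteoturn` implements the downstream quantitative analyses of a
multi-dimensional yeast proteomics design — pulsed-SILAC turnover, thermal
proteome profiling, isothermal shift contrasts, N-terminal acetylation
classification, and the surrounding moderated statistics — together with
synthetic-data generators that realize the statistical model each stage
assumes. This note records the models, the defaults and why, the numerical
choices, and what passing tests do and do not demonstrate.

## Pulsed-SILAC turnover model

During a chase from heavy to light lysine, the pre-existing heavy pool of a
protein is lost with first-order kinetics at the total rate
`k = Kdeg + Kdil`: selective intracellular degradation plus unselective
dilution by cell growth. The heavy fraction (relative isotope abundance)

    RIA(t) = H/(H+L) = r/(1+r),   r = H/L

follows `RIA(t) = A exp(-k t)`, so `ln RIA` is linear in time. Each
protein × strain × replicate series is fit by ordinary least squares on
`(t, ln RIA)` using points with `0 < t <= 6 h` and `RIA > 0`; `k` is the
absolute slope and the half-life `t1/2 = ln 2 / |k|` (the time at which the
protein is half-labeled). A `t = 0` sample carries no information
(`ln RIA = 0` by construction) and is excluded. Series with fewer than two
unique peptides or fewer than four valid timepoints are discarded before
fitting. Replicate fits are combined by averaging `k` over replicates that
pass QC; quality control requires a negative slope and `r² >= 0.8`
(configurable — "high confidence" is not otherwise quantified). Positive
slopes (apparent label gain) are flagged rather than raised, and such
series are silently excluded from comparisons.

**Dilution constant.** The strain growth rate is estimated from the decay
of the proteome-median RIA: per replicate, the median RIA across proteins
is computed at each timepoint and `ln(median RIA)` is regressed on time;
the replicate `Kdil` estimates are cleaned by the MAD outlier rule
(below) and averaged (mean; the median was the alternative). The doubling
time is `Tdil = ln 2 / Kdil`. This procedure is exact when the median
protein does not degrade: if all `Kdeg = 0`, median RIA is
`exp(-Kdil t)` and the estimate is unbiased at any noise level (the noise
enters symmetrically on the log-ratio scale, and medians are invariant
under the monotone ratio→RIA map). When degradation is present the median
RIA decays at `Kdil + median(Kdeg)`, so the procedure carries a positive
bias equal to the median degradation rate. Under the generator's default
degradation distribution (median 0.05/h) this bias is material:
the recovered doubling time is `ln2/(Kdil + 0.05)` (≈1.7 h for a true
1.9 h), and a two-strain growth-rate contrast is compressed from ~28% to
~25–26%. The acceptance script reports these honestly computed values; the
bias is a property of the median-RIA procedure itself, visible precisely
because the generator exposes ground truth.

**Growth normalization.** The two-compartment split `k = Kdeg + Kdil` is
inverted as `Kdeg = max(k - Kdil, 0)` and turnover is reported as the
dimensionless `theta = Kdeg / Kdil` (0 = pure dilution, 1 = degradation at
the growth rate). The subtraction form is an interpretive choice: the
normalized quantity is plotted as a ratio in the source framework but the
subtraction is never written out; a `mode="divide"` flag provides the
alternative reading `theta = k / Kdil`.

**Half-life shift model.** For a WT half-life `t` under dilution
`Kdil_wt`, the degradation component is `Kdeg = max(ln2/t - Kdil_wt, 0)`
and the predicted half-life under `Kdil_alt` is `ln2/(Kdeg + Kdil_alt)`.
Identity, monotonicity and the long-/short-lived limits hold on the
model-consistent domain `t <= ln2/Kdil_wt`; longer apparent half-lives
imply a negative `Kdeg` and are clipped to the dilution-only bound.

## Thermal proteome profiling

Soluble abundance across the gradient is modeled with the four-parameter
log-logistic curve

    f(T) = d + (a - d) / (1 + (T/T50)^b)

with upper plateau `a`, lower plateau `d`, inflection slope `b > 0` and
midpoint `T50`; `f(T50) = (a+d)/2` identically, and the melting temperature
`Tm = T50`. The `(T/T50)^b` form (log-logistic in the temperature ratio) is
retained rather than the `exp(b(T - T50))` logistic common in other TPP
tools. Fits require at least 8 points, run on reference-scaled linear
abundances by default (every value divided by the lowest-temperature
abundance — a deliberate stand-in for a full variance-stabilizing
normalization, with raw fitting available via `scaled=False`), and use
bounded trust-region least squares (`a ∈ [0.3, 1.5]`, `d ∈ [0, 0.8]`,
`b ∈ (0, 500]`, `T50` within the sampled range ±5 °C) with multi-start
initialization: `T50` at the half-range crossing and ±3 °C, `b` at
{10, 35, 80}; best residual sum of squares wins; tolerances 1e-8, at most
1000 function evaluations per start.

**MAD rule.** A value is an outlier when `|x - median| > k_mad * MAD`,
where MAD is the unscaled median absolute deviation; when MAD = 0 any value
different from the median is flagged. The default `k_mad = 1.0` is the
literal reading of "outside the MAD range" and is unusually strict —
roughly ±0.67 standard deviations for normal data — so it is configurable.
Consensus Tm per protein/strain is the median of the MAD-surviving
replicate T50 values.

**ITSA.** Soluble and precipitated fractions are contrasted against the
lowest-temperature reference (25 °C): `log2(abundance at T / abundance at
reference)` per protein, fraction and replicate, followed by the volcano
statistics per temperature and fraction. Default simulation gradient: 10
temperatures from 37 to 67 °C; the ITSA design uses four temperatures
spanning 38.3–49.9 °C plus the reference.

## N-terminome classification

Only peptides matching the annotated protein at residue 1 (initiator Met
retained) or residue 2 (iMet cleaved) count as N-terminal evidence;
coordinates are 1-based. Classes partition every valid terminus:

* NatA — start 2 and first residue in {A, T, S, V, G}. Cys is deliberately
  excluded because the source substrate list omits it (canonical NatA
  includes it); the residue set is an argument.
* NatB — start 1 and +2 residue in {D, N, E, Q}.
* NatC-type (incl. NatE overlap) — start 1 and +2 residue in {L, F, I, W};
  only Met-Phe/Met-Leu are canonical, Ile/Trp added per standard NatC
  specificity and configurable.
* unclassified — everything else (including Pro at +2, which is
  NME-cleaved but never acetylated; giving it its own class was considered
  and deferred).

Redundant observations collapse to one row per (protein, start position,
genotype) — position-level, not sequence-level, non-redundancy — with
"acetylated in any observation" as the terminus-level flag. Summaries
report the acetylated fraction per genotype, the NatA share among
acetylated termini, and the relative reduction `(f_WT - f_KO)/f_WT`.
The matched-pair operation selects NatA termini acetylated in WT and
unmodified in the knockout, the operational definition of NatA substrates
for turnover comparison. Sequence-window exports (first 5 residues,
counts and two-group frequency differences) feed logo rendering, which is
out of scope.

## Intensity matrices

Rows are kept when strictly more than half of one condition's values are
valid (a row at exactly 50% everywhere is dropped). Missing values are
imputed per sample from `Normal(mean_obs - 1.8 sd_obs, (0.3 sd_obs)^2)`,
the left-censored convention; observed cells are never overwritten and the
imputation mask is returned. Whole-matrix imputation was the alternative;
per-sample is the established default. iBAQ divides the summed qualifying
peptide intensity by the count of theoretically observable peptides from a
positional in-silico digest (trypsin `[KR]` not before P, or Lys-C after
K; default length 7–30, 0 missed cleavages — neither the length range nor
the missed-cleavage policy is specified upstream, these are the common
defaults). The newly-synthesized mode qualifies only light-channel,
lysine-containing peptides — the signature of proteins translated after a
light-lysine pulse in a Lys-C digest, which is why the digest default for
that mode is Lys-C.

## Differential statistics

The moderated statistic is `d = (mean_b - mean_a)/(se_pooled + s0)` with
the pooled-variance (Student) standard error and `s0 = 0.1` on the analysis
scale; at `s0 = 0` it is exactly the classic two-sample t. Significance
uses a SAM-style permutation scheme with 250 label randomizations by
default: distinct label arrangements only (complements deduplicated when
group sizes are equal, the observed labeling excluded), exhaustive
enumeration when fewer distinct arrangements exist than requested. For a
cutoff `c`, `FDR(c) = mean over permutations of #{null |d| >= c} /
#{observed |d| >= c}`, capped at 1; a feature's q-value is the minimum FDR
over cutoffs it passes, and tiers are assigned at 1% and 5%. The exact
volcano-curve construction used by Perseus is undocumented, so tier
membership — not curve geometry — is the contract here. With only 2–3
replicates per group the permutation null is very coarse (few distinct
arrangements); the machinery warns and uses what exists.
Benjamini–Hochberg adjustment (NaN pass-through) is provided for the
classical p-values.

## Synthetic data

The generators realize the study conditions: six chase timepoints
{0.5, 1, 2, 3, 4.5, 6} h (the sampling design states six points within
two–three doublings of a 1.9 h cycle without listing them; these are
even coverage of that window), WT dilution constant `ln2/1.9 ≈ 0.365`/h,
degradation rates log-normal (meanlog `ln 0.05`, sdlog 1.0 — a long right
tail with median half-life ≈ 14 h), multiplicative ratio noise of sd 0.1
on `ln(H/L)`, ten melt temperatures 37–67 °C with T50 ~ Normal(48, 3) °C
and relative noise sd 0.03, and genotype-dependent acetylation
probabilities (NatA 0.9 → 0, others genotype-invariant). Ratios are
emitted as (H, L) intensity pairs so the `t = 0` boundary (L = 0, ratio
undefined) is representable. The generator's iMet-cleavage rule is the
N-end methionine-excision rule (position-2 residue in {A,C,G,P,S,T,V}),
broader than the NatA substrate set. Ground truth accompanies every table;
identical configs give byte-identical output.

What the generators do **not** emulate: peptide-level identification
errors, retention-time or spectral structure, ratio compression,
protein-group ambiguity, batch effects, or correlated missingness.
Passing tests therefore demonstrate correctness of the estimators under
their own assumptions — unbiasedness, calibration, recovery of injected
effects — not robustness to the full error structure of real MS data.

## Problem sizes and determinism

Test and acceptance runs use 40–500 proteins, 2–4 replicates and 20–250
randomizations; these sizes give stable Monte-Carlo behaviour for every
asserted quantity while keeping the suites quick. All randomness flows
through explicit seeds (`numpy.random.default_rng`); the run manifest
echoes seed and parameters so any run can be reproduced bit-identically.

## Known limitations

* The median-RIA dilution estimator is biased upward by the median
  degradation rate (see above); with real proteomes the bias is small only
  when the median protein is long-lived relative to the cell cycle.
* Variance-stabilizing normalization is not reimplemented;
  reference-scaling is a stand-in and externally normalized intensities
  can be supplied directly.
* The permutation FDR is coarse at very small replicate counts — an
  inherent limit of label permutation, not of the implementation.
* Peptide-to-protein aggregation for peptide-level input uses the median
  peptide ratio per protein and timepoint; vendor protein-level ratios are
  used as-is when present.
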