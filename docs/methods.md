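# Methods

## Isotopomer model

Every analysis in this package rests on a carbon-only binomial
isotopomer model. A fragment is described by three integers: analyte
carbons, labelable carbons, and derivatization carbons (`FragmentSpec`).
Within one molecular population, each labelable position carries ¹³C
independently with probability *p* (the population's isotopic
abundance), so the population's MID over the labelable positions is
Binomial(n_labelable, p). All other carbons — positions the tracer
cannot reach, plus carbons added by derivatization (the FAME methyl, TMS
groups) — are independent Bernoulli(p_nat) trials, giving a
Binomial(n_background, p_nat) background; the fragment MID is the
convolution of the two. An observed MID is a convex mixture of
population MIDs. Consequences used throughout:

- a population with p = p_nat is indistinguishable from natural
  abundance over the whole fragment (binomial additivity);
- the mean mass shift of any mixture is exactly
  Σ f_j·n_labelable·p_j + n_background·p_nat (first-moment conservation,
  the main invariant checked by the property tests);
- distributions are finitely supported on 0..(total carbons); no
  truncation or renormalization correction is ever needed.

Labelable-position counts encode the tracer chemistry: bicarbonate
labeling (photosynthate) can reach every analyte carbon, while
[2-¹³C]acetate contributes only the C2 carbon of each acetate unit, i.e.
the even-numbered acyl carbons — N/2 positions for a fatty acid of N
carbons, 7/8/9 for 14:0/16:0/18:0. Only carbon isotopes are modeled;
H/O/Si natural abundance in TMS/FAME derivatives is ignored, and the
shipped fragment set uses zero derivatization carbons (a backbone-only
analysis). Fragments with explicit derivatization carbons are supported
for users whose spectra are not pre-corrected; whether the original
spectral software corrected for derivatization carbons is not
documented, so neither mode is asserted as "the" published one.

p_nat defaults to 0.0107 (representative terrestrial ¹³C abundance) and
is configurable everywhere.

## Deconvolution

Two estimators invert the mixture:

**Stripping (default).** The unlabeled fraction is the largest α ≤ 1
with observed − α·natural ≥ −tol elementwise (tol = 1e−9; configurable
for noisy data). The clipped, renormalized residual is the labeled
component; each residual shift k is assigned the nominal abundance
p_k = k / n_labelable (capped at 1), and mass at shifts with p_k
strictly above the threshold (0.5) is the highly-labeled fraction.
Negative residual entries from noise are clipped and the clipped mass is
reported as the result's `residual_norm`. The strict inequality matters:
on a six-carbon sugar, shift 3 has p_k = 0.5 exactly and is *not* highly
labeled.

**Grid fit.** Nonnegative least squares (Lawson–Hanson, scipy) over a
design matrix of candidate population MIDs: the natural population plus
one column per grid abundance (default 0.05..1.00 in 0.05 steps).
Weights are renormalized to sum to 1; fitted fractions below 1e−4 are
dropped; duplicate grid entries are deduplicated with a warning. Because
the columns are Bernstein-basis evaluations, mixtures of a few
populations are identifiable and noiseless grid mixtures are recovered
to numerical precision.

The two estimators answer subtly different questions — nominal per-shift
abundance versus fitted population abundance — and agree (within one
percentage point) only when the labeled population's binomial mass is
concentrated on one side of the threshold, i.e. p well above 0.5 at the
fractions of interest. A population at p ≈ 0.7 straddles the threshold
under per-shift classification, the same ambiguity as low-shift sugar
isotopomers whose k/N sits at exactly 0.5. Both estimators are exposed
and the agreement test is scoped to the concentrated regime.

## Rates

The rate conversions are the printed tables' footnote formulas, applied
at full precision with round-half-even rendering at each printed cell's
decimals:

- incorporation rate [C] = content [A] × labeled fraction [B]/100, per
  labeling hour (label time defaults to 1 h, matching the experiments);
- turnover rate [D] = −ln(1 − [B]/100)/t, the exact inverse of the
  steady-state pool model f(t) = 1 − exp(−kt); it is convex, exceeds
  f/100 everywhere, and approaches it for small fractions;
- lipid carbon content = carbon number × content/1000 (μmol C·mg⁻¹ chl)
  and specific radioactivity = incorporation/carbon content (×10⁻⁶);
- fatty-acid C2 content = content × C2 units and specific radioactivity
  = 1000 × incorporation/C2 content (×10⁻⁶);
- degradation rate = turnover − μ, floored at zero with a `below_growth`
  flag rather than an error, because in vitro turnover can legitimately
  fall below the growth rate (arrested downstream metabolism);
- μ = ln 2/doubling time (0.0578 h⁻¹ for 12 h);
- dpm → pmol uses 2.22×10⁹ dpm·mCi⁻¹ and the substrate specific
  activity (58.8 mCi·mmol⁻¹ default); this conversion is provided as
  plumbing, not asserted as the original workflow's path.

All quantities are per mg chlorophyll; no per-cell normalization is
attempted. Fractions ≥ 100% are domain errors (a finite observed
fraction cannot imply complete replacement under this model).

## Printed-table reproduction

The packaged fixtures carry each published table's input columns and
printed derived cells, with provenance comments. `reproduce-tables`
recomputes every derived cell and diffs at printed precision
(round-half-even, decimals read off each printed string). Four printed
cells disagree with their own footnote formulas applied to the printed
inputs and are recorded in `printed_anomalies.csv` as expected
mismatches — all four are consistent with the source using unrounded
intermediate fractions. "nd" (not detected) cells are encoded as
missing, propagate as missing, and are excluded from diffs. The diff
report is the single acceptance surface: anything other than the
enumerated anomalies fails (nonzero exit).

## Synthetic data

The generator emulates the measurement process the analysis assumes: a
steady-state pool turning over at rate k has labeled fraction
1 − exp(−kt) at each timepoint; newly synthesized molecules form one
labeled population; the observed MID is the mixture, optionally with
multinomial ion-counting noise (`n_ions` total ions; the study reports
no ion counts, so noise levels are scenario parameters, not defaults —
the shipped scenarios are noiseless). It does not simulate
chromatographic baselines, spectral overlap, or lipid-class
interconversion. Randomness is a single seeded generator with
per-fragment substreams derived by hashing fragment names, so adding a
fragment never perturbs another fragment's draws, and identical
scenario + seed gives byte-identical outputs.

The shipped calibration scenarios mirror the published experiments: 1-h
bicarbonate labeling of galactose/glycerol/16:0 at k = 0.092/0.063/0.073
h⁻¹ (intact cells) and 1-h acetate labeling of 14:0/16:0/18:0 at
k = 0.023/0.005/0.038 h⁻¹ (isolated plastids). The labeled population
uses p = 1.0 — fully labeled de novo material, idealizing the 99% ¹³C
substrate — so the highly-labeled fraction coincides with the true newly
synthesized fraction and the noiseless pipeline inverts k exactly; a
scenario may set any other `label_p`, at the cost of the per-shift
classifier then undercounting mass that leaks below threshold.

Passing these tests shows the pipeline inverts its own forward model —
including under realistic counting noise (at 10⁵ ions, median recovered
k is within a fraction of a percent of truth over 100 seeds). It does
not validate the binomial mixture assumption itself against real
spectra, nor chromatographic artifacts outside the model.

## Numerical choices and limitations

- MID normalization tolerance 1e−9; normalized inputs are required by
  convolution and deconvolution and violations raise, not warn.
- Stripping cap α ≤ 1 prevents noise from implying a >100% unlabeled
  pool.
- Rounding for table comparison is round-half-even via `decimal`, on the
  repr of the float, avoiding binary-representation surprises.
- Problem sizes in the test suite (100–200 seeded replicates at 10⁵
  ions, 20-seed batches for noise-scaling checks) were chosen to make
  the Monte-Carlo claims stable from run to run at second-scale cost.
- Per-position (positional isotopomer) labeling, Bayesian uncertainty on
  p, mzML peak picking, and isotope correction for elements other than
  carbon are out of scope.
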