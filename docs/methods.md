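# Methods

This note records the models, conventions and numerical choices behind
the package, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Spectrum model and window operations

A spectrum is a chemical-shift axis in ppm (stored descending, the NMR
display convention) with an intensity vector in arbitrary units and the
proton Larmor frequency in MHz (defaults: 600.13 MHz for
high-resolution extract spectra, 300.3 MHz for 7 T in vivo spectra).
Windows are always given as `(lo, hi)` with `lo < hi` regardless of
storage order.

**Referencing** rigidly shifts the axis so the tallest local maximum
within ±0.2 ppm (configurable) of the anchor lands on the anchor —
chloroform at δ = 7.26 for extracts in CDCl₃, water near 4.7 ppm for
in vivo spectra. Ties between equally tall maxima break toward the
anchor. The operation is idempotent to within one grid step.

**Baseline and integration.** Interactive "peaks"-style integration in
vendor software is replaced by a deterministic rule: within each
window, subtract the straight line through the mean intensity of the
outermost samples at each edge, then integrate by the trapezoidal rule.
Each edge region spans one tenth of the window's samples (minimum 3).
The fraction-based edge was chosen over a fixed 3-point edge because a
3-sample mean has a variance that does not shrink as the grid is
refined; at realistic noise levels it alone would dominate the error of
small peak areas, whereas a fixed fraction gives a baseline estimator
whose variance vanishes with grid density and is identical on noiseless
data. Negative integrals are floored at zero (areas feed ratio formulas
where negativity is nonphysical); a warning is emitted unless the
deficit is numerical dust.

**FWHM** is estimated from the apex of the baseline-corrected window
and the two half-maximum crossings located by linear interpolation
between bracketing samples, reported in both ppm and Hz
(`fwhm_hz = fwhm_ppm × spectrometer_freq`). On analytic lineshapes the
error is bounded by one grid step and halves when the axis density is
doubled.

**File formats.** JCAMP-DX (AFFN `(XY..XY)` and `(X++(Y..Y))` tables;
compressed SQZ/DIF forms are rejected with a clear error) and a
two-column TSV dialect whose `#`-prefixed header lines carry
acquisition metadata as `key=value`. Both round-trip at 12 significant
digits.

## Proton stoichiometry and the resonance catalog

An acyl chain of length L with d methylene-interrupted double bonds
carries 2L−1−2d protons from C2 to the terminal methyl, partitioned as:
olefinic 2d (5.3 ppm), diallylic 2·max(d−1, 0) (2.8 ppm), allylic 4 if
d ≥ 1 (2.0 ppm), α-carboxyl 2 (2.25 ppm), β-carboxyl 2 (1.6 ppm),
terminal methyl 3 (0.98 ppm for ω-3 chains, 0.90 ppm otherwise), and
the bulk (CH₂)ₙ remainder at 1.3 ppm. Head-group markers contribute 4
(TG glycerol, 4.12–4.30 ppm), 9 (choline, 3.48 ppm), 2 (PE, 3.40 ppm)
and 3 (cholesterol C18, 0.68 ppm) protons per molecule. The two
terminal-methyl windows split at 0.94 ppm; this split is a convention —
in real spectra the 0.90/0.98 signals partially overlap and the
apportioning is imperfect.

These counts are the closed-form oracle for the simulator: expected
area = scale × Σ concentration × fraction × protons, with no lineshape
involved.

## Fatty-acid composition indices

Index definitions are configuration data (name, numerator and
denominator as peak/coefficient lists, offset, optional floor). The
shipped defaults are forced by the stoichiometry above, with A₀.₉ (3
protons per non-ω-3 chain) as the per-chain denominator:

| index | formula | pure 16:0 / 18:1 / 18:2 |
|---|---|---|
| ndb  | 1.5·A₅.₃/A₀.₉ | 0 / 1 / 2 |
| SI   | A₁.₃/A₅.₃ | undefined / 10 / 3.5 |
| UFA  | 0.75·A₂.₀/A₀.₉ | 0 / 1 / 1 |
| SFA  | 1 − UFA | 1 / 0 / 0 |
| PUFA | 1.5·A₂.₈/A₀.₉ | 0 / 0 / 1 |
| MUFA | UFA − PUFA (floored at 0) | 0 / 1 / 0 |
| MCL  | 1.5·(A₁.₃+A₁.₆+A₂.₀+A₂.₂₅+A₂.₈+2·A₅.₃)/A₀.₉ + 2 | 16 / 18 / 18 |

The MCL numerator counts the olefinic area twice: each olefinic CH
carries one proton where a saturated chain would carry two, so
2L−4 = (non-methyl protons) + (olefinic protons) — with a single
olefinic term the formula would understate the length of unsaturated
chains by d carbons. Undefined indices (zero denominator, e.g. SI of a
fully saturated pool) propagate as missing values, never zeros, and are
excluded pairwise by the statistics.

Two caveats. First, these defaults are *per-chain* quantities derived
from proton counting; published index values from other fitting
pipelines need not match them in absolute terms, so the definitions are
deliberately configuration, not constants. Second, ω-3 chains move
their methyl out of the A₀.₉ denominator; on ω-3-rich pools the
0.90-based indices overshoot (UFA can exceed 1). In vivo this is moot —
ω-3 methyls are not resolvable at 7 T — but it is the reason the index
engine reports rather than clamps.

## In vivo measurands

IHLC is the baseline-corrected area ratio of the bulk methylene window
(1.15–1.45 ppm) over the water window (4.2–5.2 ppm) in the
*unsuppressed* voxel spectrum; zero water area raises an acquisition
error rather than returning infinity. The TG index integrates the
glycerol windows 4.05–4.15 and 4.25–4.35 ppm of the *suppressed*
spectrum and divides by the 4 contributing protons. The water FWHM is
reported in Hz (and ppm); iron loading broadens the water line by
shortening T2, so the linewidth serves as an indirect iron proxy. All
windows are configuration constants in one place.

## External-standard quantification

`Conc_met = Conc_st·A_met·m/(A_st·m_st)` with `m = T·P1/(RG·NS)`. The
standards registry ships as a synthetic stand-in with the structure of
an in-house database (21 molecules, 11 classes; 10 mM everywhere except
the TG standard at 36.7 mM). Reference areas are *not* stored: each
representative standard solution is simulated noiselessly at load time
and its marker window integrated, so the registry and the simulator
cannot drift apart, and the m-factor correction is exercised whenever
sample and standard acquisitions differ. One representative standard
per class is used because combining multiple standards per class is an
open design choice; the representative is config-selectable.
Concentrations are reported per mg dry weight for liver and per mg
fresh weight for adipose tissue; switching basis rescales by the weight
ratio exactly.

## Statistics

The normality gate uses the Lilliefors-corrected Kolmogorov–Smirnov
test: with n = 5–6 and parameters estimated from the sample, the plain
KS test against fitted parameters is anti-conservative. Groups with
n < 4 pass the gate (no testable evidence against normality);
zero-variance groups fail it and fall through to Mann–Whitney. The
t-test is Welch by default (pooled available); Mann–Whitney uses the
exact null distribution for groups of ≤ 8 without ties, the normal
approximation otherwise. Under the null at n = 5 the gated procedure is
slightly conservative (empirical size ≈ 0.044 over 10⁴ replicates),
because the Mann–Whitney branch cannot reject at exactly 0.05 with tiny
groups. No multiple-testing correction is applied by default, matching
per-measurand table reporting; Benjamini–Hochberg is available.

PCA preprocessing order is: rows divided by row totals (total-area
normalisation), columns mean-centred, columns divided by √SD (Pareto
scaling), then SVD. Component signs are fixed by making each
component's largest-magnitude loading positive. Columns constant after
normalisation are dropped with a warning; a fully degenerate matrix
returns zero scores and zero explained variance.

## Synthetic-data generator

Lines are rendered as area-normalised Gaussians by default, one line
per catalog resonance at its nominal shift (HR-NMR default FWHM
0.01 ppm; MRS lipid lines 0.02 ppm ≈ 6 Hz at 7 T; tunable). A
Lorentzian option exists, but Gaussian is the default for two reasons:
processed experimental spectra are Gaussian-apodised, and Lorentzian
tails place >10% of a line's area outside the narrow catalog windows,
which would make window integrals systematically disagree with the
closed-form areas. The simulated extract signal is scaled by
RG·NS/(T·P1) — the reciprocal of m — so that external-standard
quantification must apply the acquisition correction non-trivially;
this is a simulator convention, not a receiver model. Noise is white
Gaussian, specified as a fraction of the maximum noiseless signal, and
seed-deterministic. The default extract axis is 16384 points over
−1 to 11 ppm; the MRS axis is 8192 points over a 15 ppm width centred
near water (a reconstructed, zero-filled grid; the raw acquisition grid
is coarser).

The voxel-pair simulator renders a unit-area water line at 4.7 ppm with
the requested FWHM, lipid lines scaled so A(1.3)/A(water) equals the
requested lipid fraction, and TG glycerol signal split between 4.10 and
4.30 ppm; suppression attenuates water by 10³.

Cohorts are drawn per animal from group Normal(mean, SD) truncated at
zero, with the packaged group tables (n = 5 per genotype × age) as the
default study conditions. Rendered spectra are consistent with the
constructive measurands (class concentrations; IHLC, TG and water FWHM)
but not with the drawn index values — seven indices over-determine the
eight acyl areas — so the indices live in the cohort table only.

What the generator does **not** emulate: J-coupling and multiplet
structure, relaxation and echo-time weighting, frequency-dependent
phase or baseline roll, solvent artefacts, voxel partial-volume
effects, and peak-position drift. Passing tests therefore demonstrate
the correctness of the quantification arithmetic and the statistical
machinery under the stated noise model — not robustness to the full
pathology of in vivo data.

## Numerical choices and degenerate inputs

Integration requires ≥ 4 samples per window; fewer raises a resolution
error. Window integrals are floored at zero. The SNR-50 quantification
check runs on a dense (2²²-point) axis: at 2% peak-height noise the
baseline-edge variance is the limiting term for minor-class areas, and
the dense grid keeps the worst-case class error near 1–3%. Minor
classes two orders of magnitude below the bulk signal (PE, PC+LPC at
liver-like levels) cannot be recovered to 5% from a single SNR-50
spectrum with any window integrator; the round-trip check at that noise
level accordingly uses concentrations of comparable magnitude, while
the liver-level TG recovery is demonstrated at its published
0.2011 mM·mg⁻¹ value. All simulation problem sizes used by the tests
and the acceptance script (100 mixtures, 10⁴ null replicates, 10³ power
cohorts, 200 PCA seeds, n = 5 groups) were chosen to estimate each rate
comfortably inside its tolerance.

## Limitations

Window integration is not basis-set fitting: overlapping resonances
(diallylic vs α-carboxyl shoulders, 0.90/0.98 methyls) are
apportioned by fixed window bounds, and the bounds themselves are
tunable configuration, not measured constants. Absolute index values
depend on those bounds and on the per-chain conventions above. The
standards registry is synthetic; quantifying real spectra requires
replacing it with measured standard areas. FWHM is reported in both Hz
and ppm since either convention appears in practice.
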