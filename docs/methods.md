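# Methods

`nirfly` implements a near-infrared (NIR) chemometrics workflow for
phenotyping individual Drosophila from reflectance spectra: species
(D. melanogaster vs D. simulans), sex, age in days after eclosion, and
Wolbachia infection status. This note records the model, the numerical
choices, and what the synthetic data can and cannot show.

## Measurement model and preprocessing

The working unit is apparent absorbance A = log10(1/R), computed from
reflectance R in (0, 1]. Spectra live on a uniform wavelength grid
(350–2500 nm at 1 nm in the default design; 2151 points). The fixed
preprocessing chain is

1. **Region restriction** to the closed interval 500–2200 nm (1701
   points). Instrument noise rises sharply outside this region, and
   including it degrades the calibration.
2. **Savitzky–Golay (SG) first derivative** (optional, per task): each
   point is replaced by the analytic first derivative of the local
   least-squares polynomial of degree 2 fitted to a sliding window, scaled
   per nm so results are independent of grid spacing. The half-window of
   points at each grid edge is *dropped*, not extrapolated — no fabricated
   support influences the model, at the cost of a slightly shorter grid.
   The polynomial degree (2) is the common chemometrics choice for first
   derivatives and is exposed in `PreprocessConfig`.
3. **Mean centering** on the *calibration* mean. Independent spectra are
   always centered by the calibration statistics, never their own — the
   centering vector belongs to the fitted model.

Per-task presets: species uses a 45-point SG window, age and Wolbachia use
35 points, and the sex model uses no derivative at all (the derivative was
found to hurt that task). The order restrict → derivative → center is
fixed; deriving before restricting would let the noisy grid edges leak
into windows near the region boundary.

## PLS1 calibration

Each trait is calibrated with single-response partial least squares
regression computed by NIPALS. For centered X (n × p) and y:

    for a = 1..k:
        w_a = X'y / ||X'y||     t_a = X w_a
        p_a = X't_a / (t_a't_a) q_a = y't_a / (t_a't_a)
        X ← X − t_a p_a'        y ← y − q_a t_a

PLS1 NIPALS is deterministic (no iteration, no random start). The factors
collapse into b = W(P'W)⁻¹q so a new spectrum predicts as
ŷ = (x − x̄)·b + ȳ. Extraction stops early if the residual covariance
‖X'y‖ falls below 1e-13 of its initial value (degenerate response), in
which case the model keeps the factors it has.

Binary traits are dummy-coded (species 1/2, sex 3/4, infection 5/6) and
the continuous prediction is thresholded at the code midpoint (1.5 / 3.5 /
5.5); a prediction *equal to or greater than* the cut-off takes the
high-code class. Age is regressed directly in days and graded into young
(< 9 d), middle (9–18 d, boundaries included) and old (> 18 d), plus the
< 9 vs ≥ 9 dichotomy. Predictions are never clamped: a negative predicted
age is simply graded young, and cohort means stay honest.

### Factor selection

The factor count is chosen from the PRESS curve of a leave-one-out
cross-validation: each fold re-centers and refits on the n−1 retained
flies and predicts the held-out fly. The selected k is the *smallest*
count whose PRESS is within 2% (configurable) of the curve minimum —
parsimony before marginal gains. Selection uses calibration PRESS only;
the independent set never influences it (selecting on test accuracy, an
alternative sometimes seen, leaks the validation data). `k_max` defaults
to 20, a conventional chemometrics cap.

The LOO implementation is exact but does not materialise n refits. The
NIPALS recursion depends on the data only through X'X and X'y (the kernel
form: t_a't_a = r_a'(X'X)r_a, p_a = (X'X)r_a / t_a't_a, with
s = X'y deflated as s ← s − (t't)q_a p_a and r_a the Gram–Schmidt image of
w_a against previous loadings). Each fold's centered cross-products are
rank-one downdates of the full ones:

    A_{-i} = A − c·x_i x_i',  s_{-i} = s − c·y_i x_i,  c = n/(n−1)

(working in globally centered coordinates), so all n folds advance one
factor at a time with a single p × p by p × n matrix product. The test
suite enforces equality with an explicit refit loop to 1e-10 (observed
agreement ~1e-14). Full-scale runs (n = 2520, p ≈ 1657, k_max = 20)
complete in seconds; peak memory is the 2·k stored p × n factor arrays.

### Outlier screening

After factor selection, calibration flies are screened once: Mahalanobis
distance of the latent scores from the score centroid, using the
calibration score covariance (ddof = 1), with the spectral reconstruction
residual ‖x_c − tP'‖² reported alongside. Flies with distance strictly
greater than 3 are dropped and the model is refitted once — no iterative
re-flagging, so the procedure is deterministic and auditable. If more than
20% of the calibration would drop, a warning is attached and the model is
still returned. Distance is computed in score space (not on raw spectra)
and on the distance scale (not squared); both conventions are
parameterised. The screen never touches independent flies.

## Study designs

* **species** — one model on all four calibration lines × 7 cohorts
  (2520 flies), validated on distinct Dah/Ky flies at 5/13/21 d.
* **gender** — one model per species, trained on the Alst (resp. Hw)
  line, validated on Dah (resp. Ky).
* **age** — four models, one per calibration line × sex (315 flies each),
  validated on the matching independent line and sex.
* **wolbachia** — one model on infected/uninfected pairs of two
  D. simulans lines scanned at 15 d (300 calibration, 120 independent).

Calibration and validation sets are disjoint by construction and any
sample-id overlap is a hard error. Reports contain per-class accuracies in
percent, confusion tables, and for age the per-cohort mean ± SD of
predicted age, bin and dichotomy accuracies, and the least-squares
regression of predicted on actual age (r² = squared Pearson correlation).
Age regression statistics are reported from the cross-validated
calibration predictions, the honest analogue of a calibration scatter
plot; fitted-value regressions would flatter the model as k grows.

## Synthetic populations

The generator emulates the study conditions, not fly physiology. Each
spectrum is baseline + per-fly scatter offset + six Gaussian absorption
bands (1225, 1390, 1450, 1540, 1570, 1620 nm; lipid CH and water OH
overtone regions) + heteroscedastic instrument noise (SD 0.0015 inside
500–2200 nm, 0.010 outside). Band amplitudes are linear in per-fly latent
traits:

* a species latent (class means ±0.5, SD 0.21) loading on the lipid bands;
* a sex latent (±0.5, SD 0.25) on the water bands;
* an infection latent (±0.5, SD 0.22) on water/lipid bands;
* a physiological-age latent t_eff = age + N(0, 2.8 d) driving a mildly
  saturating response g(t) = t + 2.5·(1 − e^(−0.2 t)) on all bands
  (0.0016 absorbance/day per band), plus per-band amplitude noise
  (SD 0.002).

Independent-set lines (Dah, Ky; Hw2/Hw152 for Wolbachia) carry small
line-specific latent shifts toward the decision boundary (±0.05 / ±0.04)
and amplitude multipliers (±3%), emulating the between-line differences
that degrade cross-line prediction. These defaults were calibrated once,
while designing the generator, so the pipeline lands in the qualitative
regime of interest — binary accuracies in the low-to-mid 90s, age slope
~0.85, r² ~0.85 — and were then frozen.

Two mechanisms produce the characteristic age bias (overprediction of
young cohorts, underprediction of old ones): regression attenuation from
the physiological-age scatter (slope ≈ Var(age)/(Var(age) + σ²) ≈ 0.87
for the 1–25 d design, pivoting the predictions about the mean age), and
the concavity of the saturating band response, which compresses the old
end of the scale. Cohort means of 45 flies have a standard error of about
0.45 d, so the bias direction is assessed on cohort means pooled over the
four age models.

**What the synthetic data do not show.** Real NIR bands are broader,
asymmetric, and multiplicatively confounded with scattering; real
between-line differences are not a one-parameter shift; effect sizes here
are tuned, not measured. Passing the synthetic emulation demonstrates that
the *pipeline* recovers the structure it assumes at realistic noise — it
says nothing about how well NIRS separates real fly classes.

## Numerical details and edge cases

* Grids must be strictly increasing and uniform within 1e-9 nm; units are
  explicit (file header or override), never guessed.
* Replicate averaging is the arithmetic mean in the stored unit and
  requires internally consistent group metadata.
* PRESS ties break toward fewer factors; an empty PRESS curve, k beyond
  min(n−1, p), or a zero-variance response are errors.
* The Mahalanobis screen raises on a singular score covariance (advice:
  fewer factors). Exactly-at-threshold samples are kept.
* A constant prediction vector reports r² = 0 with slope 0.
* All randomness lives in the generator behind a single integer seed;
  the analysis path is deterministic, and identical seeds reproduce
  reports byte for byte.

## Known limitations

* PLS1 only (every task has a single response); no SIMPLS/kernel-PLS
  variants, VIP scores, or uncertainty intervals on b.
* No multiplicative scatter correction or SNV; the SG derivative is the
  only scatter treatment, as in the emulated workflow.
* Binary parsers for proprietary instrument formats are out of scope; the
  native format is CSV with an explicit units header.
* The outlier screen is single-pass by design; heavily contaminated
  calibrations may retain masked outliers.
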