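# Methods

## Scope and model structure

`mlpbpk` implements a whole-body, permeability-limited PBPK model for
intravenous dosing in an adult human, together with the evaluation machinery
(NCA, fold-error statistics) used to benchmark it. The body comprises 14
tissues and three vessel pools (arterial, venous, portal). Each tissue has
four sub-compartments — vascular plasma, vascular blood cells, interstitial
and intracellular space — linked by passive permeability–surface-area (PSA)
conductances; vessels have plasma and blood cells only. All processes are
first-order, so the state (amounts in mg) evolves as a constant-coefficient
linear ODE system; an extra "eliminated" ledger state receives every
clearance flux so that mass balance can be checked at machine precision.

Internal units are fixed (L, h, mg, mg/L, L/h); conversions happen at I/O
boundaries (Caco-2 P<sub>app</sub> in 1e-6 cm/s, CL<sub>int</sub> in
mL/min/kg, CL<sub>t</sub> in L/h/kg).

## Physiology

The packaged physiology (`data/human_default.json`) is a standard
70 kg adult: cardiac output 390 L blood/h, hematocrit 0.45, GFR 6.7 L/h,
plasma pH 7.40, blood-cell pH 7.22, intracellular pH 7.0. Tissue volumes and
flows are conventional reference values constructed so that the model's flow
invariants hold exactly: effluents of all venous-returning tissues sum to
cardiac output, and liver inflow equals hepatic arterial flow plus the
gut/spleen/pancreas (portal) effluents. Tissue composition (neutral lipid,
neutral phospholipid, intra-/extracellular water, acidic phospholipid,
tissue:plasma albumin ratio) follows the published composition tables used
by mechanistic tissue-partition methods. Because no single authoritative
table exists for the exchange surface areas, they are parameterized per
liter of tissue: 7×10⁴ cm²/L for the vascular (plasma↔interstitial)
interface, 3.5×10⁵ cm²/L for the cellular interface, and 7×10⁶ cm² per L of
blood for the plasma↔blood-cell interface. With these choices a drug with
P<sub>app</sub> ≈ 20×10⁻⁶ cm/s is near perfusion-limited in muscle while a
low-permeability drug (P<sub>app</sub> ≈ 1) is strongly permeability-limited,
which is the regime the model is designed to resolve. All values are
overridable through the JSON schema and validated on load
(`validate_physiology` reports each violated invariant).

## Tissue partitioning

Tissue-to-unbound-plasma coefficients (K<sub>pu</sub>) use the
Rodgers–Rowland composition equations. Ionization follows
Henderson–Hasselbalch; independent groups combine multiplicatively in the
neutral fraction. Compounds with any basic pKa ≥ 7 take the
moderate-to-strong base branch, in which the acidic-phospholipid association
constant is back-calculated from the blood-cell partition
k<sub>bc</sub>/f<sub>up</sub> with k<sub>bc</sub> = (BP − (1 − Hct))/Hct;
ampholytes with a weaker base take the acid/neutral branch with an
albumin-binding term scaled by the tissue:plasma albumin ratio. LogP (not
LogD) enters the neutral-lipid term and neutral phospholipid affinity is
0.3·P + 0.7. Two numerical guards:

* **k<sub>bc</sub> floor (0.01).** A measured BP at or below 1 − Hct implies
  k<sub>bc</sub> ≤ 0 (e.g. montelukast, BP 0.55 at Hct 0.45), which would put
  an infinite sink in the plasma↔blood-cell flux. The floor keeps the flux
  finite; it is configurable.
* **Protein-binding clamp.** The albumin term uses 1/f<sub>up</sub> − 1 −
  (plasma lipid partition) as the protein-binding estimate. For very
  lipophilic acids/neutrals the lipid term alone can exceed
  1/f<sub>up</sub> − 1, making the estimate (and then K<sub>pu</sub>)
  negative; it is clamped at zero with a logged warning. The same clamp
  applies to a negative back-calculated acidic-phospholipid constant.

The whole-tissue K<sub>pu</sub> terms are split between sub-compartments —
extracellular water plus albumin binding to the interstitial space; cell
water, acidic phospholipid and lipids to the intracellular space — and
converted to concentration ratios by the sub-compartment volume fractions.
This split is a convention (the composition equations constrain only the
whole-tissue coefficient); it is constructed so the volume-weighted sum of
sub-compartment ratios reproduces the whole-tissue K<sub>p</sub> exactly,
which the simulator recovers at distribution equilibrium (verified to
within 1% at t = 2000 h for moderately distributing test drugs; extremely
lipophilic compounds equilibrate far more slowly, which is physically
expected, so the equilibrium check uses moderate-K<sub>p</sub> drugs).

When a measured BP is available it is always used (and k<sub>bc</sub>
derives from it); otherwise BP is predicted from blood-cell water and lipid
composition. The predicted BP omits the acidic-phospholipid term for strong
bases, since its association constant is identifiable only from a measured
BP — predictions for strong bases are therefore conservative.

## Elimination

* **ML mode:** the predicted total plasma clearance CL<sub>t</sub>
  (L/h/kg × body weight) acts on venous plasma. This makes
  Dose/AUC<sub>venous</sub> = CL<sub>t</sub> an exact identity, used both as
  a regression test (holds to ≤0.5%; measured ≤0.04%) and to interpret the
  benchmark: NCA-derived CL in this mode reflects the quality of the
  CL<sub>t</sub> prediction, not the distribution model.
* **In vitro mode:** CL<sub>int</sub> (mL/min/kg) is scaled to whole-body
  L/h (×BW×0.06) and passed through the well-stirred liver model on blood
  clearance with f<sub>ub</sub> = f<sub>up</sub>/BP, converted back to a
  plasma-referenced clearance via BP and applied to liver vascular plasma.
  Renal clearance is unbound filtration, f<sub>up</sub> × GFR, applied to
  kidney vascular plasma. Both site assignments, and the f<sub>up</sub>
  multiplier on GFR, are documented conventions (the alternative — GFR
  without f<sub>up</sub> — is one edit in `clearance_invitro`).

## Simulation and sampling

The rate matrix is integrated with SciPy's BDF solver (rtol 1e-8,
atol 1e-10), supplying the constant matrix as the exact Jacobian. A bolus is
an initial amount in venous plasma; an infusion is a constant source over
its window, integrated piecewise. The output grid is geometric with 400
points, anchored at 1e-4 h so the vascular mixing transient (minutes) is
resolved even when the horizon spans thousands of hours. The default
horizon is seven terminal half-lives, with the terminal rate taken as the
slowest eigenvalue of the body block of the rate matrix — exact for a
linear system — floored at 48 h. This bounds the extrapolated AUC fraction
of a subsequent NCA near 2⁻⁷ (measured ≤0.8% across the benchmark); a
simpler CL/V<sub>ss</sub> estimate truncates deep-distribution compounds at
~2 half-lives and distorted their AUC by up to 26% in development, which is
why the eigenvalue rule is the default.

Clinical PK samples are drawn from an arm vein, and after a bolus the
central venous maximum overshoots what an arm sample would show, so accuracy
is evaluated on the flow-weighted vascular-plasma effluent of muscle, skin
and adipose ("peripheral plasma"). In a linear system without peripheral
elimination the peripheral AUC equals the venous AUC (tissues transmit their
full exposure), so clearances are unaffected while C<sub>max</sub> and early
shape are.

## NCA and accuracy statistics

k<sub>el</sub> is the negative slope of ln C vs t over the terminal window;
by default the window with the best adjusted R² among the last 3–10 positive
points (the window the original analysis used is not stated, so this
documented policy is the default and a fixed window can be passed). AUC and
AUMC use the linear trapezoid with the standard tail terms
(C<sub>last</sub>/k<sub>el</sub>; C<sub>last</sub>t<sub>last</sub>/k<sub>el</sub> +
C<sub>last</sub>/k<sub>el</sub>²). V<sub>dss</sub> is computed as CL × MRT —
the dimensionally consistent steady-state relation.

Fold-error statistics: AFE = 10^(mean log₁₀ FE), AAFE = 10^(mean |log₁₀ FE|),
%2FE/%3FE with **inclusive** bounds (FE exactly 2.0 counts as within
2-fold, the common regulatory reading; a strict-bounds switch exists), and
log-scale squared Pearson correlation. Note that the packaged 40-drug table
is printed to 2 significant figures, which leaves two compounds exactly on
the 2-fold boundary (midazolam for f<sub>up</sub>, diazepam for
CL<sub>t</sub>); any summary count is sensitive to the boundary convention
for exactly those rows.

## Synthetic drugs and what the tests show

`generate_synthetic_drugs` draws seeded records uniform over the benchmark's
property space — LogP ∈ [−1, 8.5], f<sub>up</sub> ∈ [0.002, 1],
P<sub>app</sub> ∈ [1, 110]×10⁻⁶ cm/s, CL<sub>t</sub> ∈ [0.01, 1.6] L/h/kg,
log-uniform CL<sub>int</sub> — cycling acid/base/neutral/ampholyte kinds. It
emulates the *parameter ranges* of real test compounds, not their joint
distribution (no LogP–f<sub>up</sub> correlation, no measurement error), so
tests passing on synthetic drugs demonstrate numerical robustness across the
input space, not predictive accuracy on new chemistry.

## ML data preparation

`mlprep` reproduces the data-engineering stages as model-agnostic
operations: curation (invalid structures, MW > 900 Da, cross-source
duplicates removed when values differ by more than 2-fold, otherwise
resolved by a configurable source-priority list), variance (< 0.05) and
pairwise correlation (|r| > 0.9, earlier column kept) feature filters,
seeded 8:1:1 splits with floor sizes, and a Boruta loop over a pluggable
importance provider (random-forest by default) with a two-sided binomial
test at α = 0.05. On a fixed finite dataset Boruta can confirm a noise
feature whose chance correlation with the target is strong in-sample; this
is inherent to the algorithm (the shadow contrast destroys correlation, the
data do not change between iterations), so the false-positive count on pure
noise is sample- and seed-dependent while a genuinely informative feature is
confirmed essentially always.

## Known limitations

* IV dosing only; linear kinetics; no transporters, lysosomal trapping,
  microsomal-binding correction, or biliary elimination.
* The physiology file is a documented stand-in assembled from standard
  reference values, not a transcription of any single published table;
  surface areas in particular set the permeability-limitation scale and are
  the least-constrained inputs.
* Composition-based partitioning is known to overestimate the distribution
  volume of extremely lipophilic compounds (LogP > 5), and predicted
  f<sub>up</sub>/LogP pairs can be mutually inconsistent, which the
  protein-binding clamp absorbs but does not repair.
* In vitro-mode clearance accuracy depends on IVIVE conventions (GFR
  scaling, microsomal binding) that vary between implementations; the
  packaged defaults systematically underpredict clearance for renally
  cleared and transporter-substrate drugs, the known failure mode of
  microsome-based IVIVE.
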