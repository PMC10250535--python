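# Methods

## Single-cell model

The cell is the Bondarenko-group mouse ventricular myocyte model in its
**apical** parameterization, which the electrophysiology literature uses
for the LV epicardium (the septal variant differs mainly in its slow
transient-outward and steady-state K⁺ currents). State vector: membrane
potential; a 9-state Markov Na_v channel (closed C_Na3–C_Na1, open O_Na,
fast-inactivated IF_Na, intermediate I1/I2_Na, closed-inactivated
IC_Na2/IC_Na3); an 8-state Markov L-type Ca²⁺ channel; a 5-state Markov
I_Kr; Hodgkin–Huxley gates for I_Kto,f, I_Kto,s, I_Kur, I_Kss and I_Ks;
instantaneous I_K1, I_Cl(Ca), background and pump/exchanger currents;
and Ca²⁺ handling with subspace, junctional and network SR compartments,
a 4-state ryanodine receptor, SERCA uptake and troponin / calmodulin /
calsequestrin buffering — 41 integrated states. Temperature (298 K) and
external ion concentrations are the published model values and are not
exposed as tunables.

One Markov state per scheme is carried as the dependent complement
(1 − Σ others), so occupancy conservation is exact by construction; the
invariant tests check the bound/positivity side. The implementation was
validated against the published quiescent initial state, which is a
fixed point of the transcribed equations to |dV/dt| ≈ 2·10⁻⁵ mV/ms, with
every Markov occupancy and gate at its published stationary value — a
strong joint constraint on all rate expressions at the resting
potential; rate behaviour away from rest is covered by the clamped
null-space and voltage-clamp tests.

### Perturbations

* **K⁺ conductance multipliers** scale the maximal conductances of
  I_Kto,f, I_Kto,s, I_Kur, I_Kss, I_K1, I_Kr, I_Ks (only the first
  three are scanned; I_K1 moves the resting potential and I_Kr/I_Ks are
  functionally minor in mouse, which the invariant tests assert rather
  than re-scan).
* **Late Na⁺ current**: the single IF_Na → O_Na re-opening rate is
  multiplied by *k*; all other transitions keep their baseline values
  (checked rate-by-rate). In this scheme the re-opening rate is the
  microscopic-reversibility rate β₂ = α₁₃α₂α₃/(β₁₃β₃); scaling it is
  exactly the "rate constant for channel re-opening" modulation.
* **I_CaL activation shift**: the two activation-ladder rates α(V) and
  β(V) are evaluated at V − ΔV½ (ΔV½ ≤ 0 moves activation to more
  negative potentials; −15 mV mimics FPL 64176). Voltage- and
  Ca²⁺-dependent inactivation are untouched, because the pharmacology
  being mimicked shifts activation. The voltage-clamp test confirms the
  I–V peak moves by the imposed amount.

## Pacing protocols

* Stimulus: rectangular 1 ms inward pulse at 30.36 pA/pF = 1.5× the
  baseline excitation threshold (20.24 pA/pF, found once by bisection;
  "excitation" = overshoot of 0 mV within 50 ms). The same relative
  strength (1.5× threshold) is used for tissue pacing experimentally.
* Integrator: LSODA (adaptive, stiffness-switching), rtol 10⁻⁶ /
  atol 10⁻⁸, integrated in stimulus-on/off segments so the pulse edges
  never fall inside a solver step. These settings are module constants;
  repeated runs are bit-identical.
* Trains: 5 s at 5 Hz (25 beats, 200 ms cycle). Features are read off
  the **last AP**, resampled to 1 ms by linear interpolation to match
  the optical temporal resolution.
* **Rate adaptation**: every perturbation run starts from the baseline
  cell's 5 Hz-adapted state (5 s pre-pace, cached), mirroring the
  experimental protocol in which slices are paced continuously and
  interventions applied during pacing. Starting perturbed cells from
  the quiescent published state is avoided deliberately: the first beat
  then carries a fully-loaded-SR Ca²⁺ transient whose Na⁺/Ca²⁺-exchange
  influx can trap strongly K⁺-reduced variants in a depolarized
  metastable state that never occurs during continuous pacing.
* Steady state: the last AP is accepted when its APD₈₀ agrees within 1%
  with the preceding **same-parity** beat (the model shows small APD
  alternans at 5 Hz, so adjacent beats alternate by design); otherwise
  the train is doubled up to 20 s, logged.
* "Up to X %" scan summaries are read at the ±50% grid endpoint, since
  the response families are monotone across the grid.
* Percent change: 100·(APD_perturbed − APD_control)/APD_control, both
  on 1 ms last-AP windows. The control grid point is exactly 0 by
  construction.
* Calibration (target APD₈₀ change → modifier factor): bisection within
  factor bounds 0.3–3.0 to ±0.25 percentage points. A factor that
  abolishes 1:1 capture or repolarization is treated as unbounded
  prolongation, which steers the search back into the valid range; a
  target outside the achievable span raises an error reporting the
  bracket responses.

## AP feature extraction

Baseline = minimum over the 30 ms preceding the upstroke (falling back
to the trace minimum when the window starts essentially at the
upstroke); amplitude = peak − baseline; APD_X = width at
baseline + (1 − X/100)·amplitude with sub-sample linear interpolation,
measured from the upward threshold crossing so simulated and optical APs
are compared like-for-like. Activation time = time of maximum first
temporal derivative, parabola-refined. All features are affine
invariant, so inverted-polarity fluorescence is simply sign-normalized
(one decision per movie, made on the mask-mean trace) before
measurement. A trace that never re-crosses its threshold raises a
dedicated "unrepolarized" error; scan drivers convert it into a
per-grid-point flag rather than a failure.

## Optical pipeline

Stage order (recorded in every result): polarity normalization →
ensemble averaging → drift correction → 3×3 spatial mean filter →
per-pixel measurement.

* **Ensemble averaging** aligns windows on the first mask-mean
  activation (window start pulled a quarter cycle earlier when
  available) and requires each cycle to correlate r > 0.8 with the
  first; misaligned pacing is an error.
* **Drift correction** fits a polynomial (default order 3) to diastolic
  samples only. Diastole is found in two passes: first everything below
  10% of the beat amplitude (guaranteeing anchors across the whole
  window — a pure percentile criterion can concentrate on one end under
  photobleaching and leave the fit unanchored), then, after the first
  subtraction, samples within max(2σ, 2% amplitude) of zero. The second
  pass expels the sub-threshold repolarization *foot* of the AP, which
  otherwise tilts the fit into the falling phase and systematically
  shortens long APDs (an APD-dependent bias that directly attenuates
  transmural gradients). A refined selection is only accepted if it
  still anchors both window ends.
* **Spatial filter**: 3×3 mean, renormalized over in-mask neighbours;
  tissue never mixes with background, out-of-mask pixels are untouched.
* **QC**: pixels with beat amplitude < 20% of the in-mask median, or
  unrepolarized traces, are flagged and excluded; > 50% failures abort
  the map.
* **Segmentation**: the cavity is the largest interior background
  component; papillary protrusions are tissue inside the cavity's
  convex hull (the short-axis cavity is convex to good approximation;
  morphological closing was rejected because it under-fills deep
  bumps), or a user-supplied exclusion mask. The free wall is the
  masked sector; the epicardial third is the outer third of the
  normalized transmural depth computed from distance transforms.
* **Transmural gradient**: per-ray least-squares slope of APD vs depth
  (endo = 0 mm), averaged over ≥ 10 valid rays; 2 px are trimmed from
  both ray ends because boundary pixels see one-sided filter
  neighbourhoods (their depth is still measured from the true
  endocardial boundary). A finite-difference radial-gradient mean is
  provided as a secondary, noisier estimate.

## Phantom generator

The phantom emulates a paced short-axis LV slice under a voltage dye:
annular wall geometry (optionally with papillary bumps), a transmural
APD₉₀ field (epicardial value + slope·depth + smooth spatial jitter),
activation delays from an epicardial stimulus site at a fixed conduction
velocity (0.35 m/s, straight-line distances), an analytic AP kernel
(sine-squared 2 ms upstroke shared by all pixels; raised-cosine
repolarization whose duration is solved in closed form so the
ground-truth APD₉₀ is exact — spatial APD variation stretches only the
repolarization phase), per-pixel gain and offset variation, shared
polynomial drift with per-pixel coefficient jitter, exponential
photobleaching (τ = 20 s), additive Gaussian noise (5% of amplitude per
frame), and inverted dye polarity. Everything is a deterministic
function of the seed.

Defaults are the study conditions: 200 ms cycle (5 Hz), 1 kHz frames,
0.05 mm pixels, male-like epicardial APD₉₀ = 69 ms with a −10 ms/mm
transmural slope (endocardium ≈ 80 ms across the 1.1 mm wall). The
female-like configuration (epicardial APD₉₀ 80 ms, slope −3 ms/mm,
larger jitter and between-animal SD) is a *synthetic* choice — no
absolute female values are printed anywhere — constrained only to be
longer, flatter and more variable than male-like. Cohorts are drawn
hierarchically (animal mean ~ Normal(group, between-SD); slice ~
Normal(animal, within-SD)) with male n = 6 and female n = 9 animals,
between-animal APD SDs of 3 ms (male, matching the 69 ± 3 ms spread) and
8 ms (female, synthetic).

The default movie is 128×128 px and 4 beats rather than the camera's
256×256 and a full multi-second recording — sizes chosen so a movie fits
comfortably in memory and the full test suite stays fast; both are
config fields. Not emulated: optics (PSF, depth averaging), motion
(experiments use an excitation–contraction uncoupler), curved conduction
paths, and Ca²⁺-dye channels. Passing phantom tests therefore
demonstrate correctness of the *processing*, not robustness to motion or
optical blur.

## Statistics

* **Nested comparison**: slices are averaged within animal; a
  two-sample t-test (pooled variance by default, Welch optional) runs
  on animal means with df = N_A + N_B − 2. This makes the animal the
  experimental unit; the Monte-Carlo null (real between-animal
  variance, identical group means) shows the nested test at the nominal
  level while naive slice-pooling is badly anti-conservative.
* **CV equality (M-SLRT)**: for k normal groups, the likelihood-ratio
  statistic for H₀ "common CV τ" is 2·Σ nᵢ log(τ̂ μ̂ᵢ / σ̂ᵢ), with the
  restricted estimates obtained by fixed-point iteration of the
  stationarity equations (μᵢ from a per-group quadratic, τ from the
  weighted residual sum). The raw statistic referred to χ²(k−1) is
  anti-conservative at slice-experiment sample sizes, so the default
  *modified* statistic applies a Bartlett correction whose factor is
  estimated by simulation from the fitted null (group means and sizes,
  common CV τ̂; 2000 draws by default, seeded). An analytic
  degrees-of-freedom variant (nᵢ → nᵢ−1, unbiased SDs) and the raw SLRT
  remain available for cross-checking. The statistic→p mapping is
  χ²(k−1); the test is scale invariant per group. Gradient CVs are
  compared on magnitudes, since slopes are signed.

## Numerical choices and degenerate inputs

* Scan grids: 0.50–1.50 in 0.05 steps (21 points, control exact);
  shifts 0 to −15 mV in 5 mV steps by default.
* Non-finite states, empty masks, missing cavities, too-few animals,
  zero-variance groups, zero-mean CVs and sub-threshold stimuli all
  raise early with specific messages; repolarization failure is a flag
  in shift scans (where it is an expected physiological outcome) and an
  error elsewhere.
* Monte-Carlo calibrations use 5000 outer replicates (binomial SE
  ≈ 0.003 at α = 0.05) with 400 inner draws per replicate for the
  Bartlett factor; single tests default to 2000 inner draws.
* All randomness flows through `numpy.random.default_rng` seeds; same
  seed, same bits.

## Known limitations

* The quantitative percent-change responses of late repolarization
  (APD₈₀) to K⁺ conductance scaling depend strongly on the exact model
  version and pacing adaptation; re-optimized descendants of this model
  lineage (fitted to tissue APDs at physiological rates, not publicly
  deposited) distribute late repolarization reserve differently —
  notably less I_Kss accumulation at 5 Hz and more I_Kto,f influence at
  APD₈₀. Directions, orderings and the early-repolarization and
  late-Na⁺ responses are robust across versions; exact magnitudes are
  not, and this package reports what the published apical
  parameterization produces.
* The published model's APDs are shorter than tissue-slice values
  (model APD₉₀ ≈ 19 ms at 5 Hz vs ≈ 69 ms optically); comparisons are
  therefore made in percent changes, never absolute durations.
* I_Kss shows ultra-slow deactivation in this parameterization and
  ratchets upward over a 5 Hz train, which is why a long-enough
  adaptation train and same-parity steady-state checks matter.
* The phantom's conduction is geometric (straight-line delays), so
  activation maps test timing extraction, not propagation physics.
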