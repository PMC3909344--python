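# Methods

## Model

Each sensor location along the gut is treated as an independent hidden
Markov chain.  The hidden variable is one of twelve mechanical muscle
states; the observation at sample *i* is (dᵢ, ḋᵢ, ṗᵢ): the diameter (mm)
and the rates of change of diameter (mm/s) and pressure (mmHg/s).  Rates
are estimated by central differences on the aligned 4 Hz grid, with
one-sided differences at the two endpoints (exact for linear traces
everywhere, including the ends).

Every state factorises into three components — a diameter component
(any/dis/occ) and one rate component each for ḋ and ṗ (quiet/pos/neg) — and
the joint emission weight of a state is the product of the three component
PMFs at the observation.  The component PMFs combine a normal bell at zero
(quiet) with normal CDF tails (pos/neg; occ/dis), jointly normalised so the
three masses sum to one for any observation.

Two deliberate simplifications are part of the model, not shortcuts:

* **Component independence.**  d, ḋ and ṗ are treated as independent given
  the state so the joint emission factorises.  No such independence holds in
  the data; it is the usual naive-factorisation simplification.
* **Constant priors.**  The emission weight uses f(o|c) ≈ f(c|o): the
  observation prior f(o) cancels in the path maximisation, and the component
  priors f(c) are *deliberately* treated as constant so that the emission
  model carries no data-estimated attributes and decodings are comparable
  across preparations.  `estimate_component_priors` computes the empirical
  priors anyway (the sample average of f(c|o), equivalent to kernel-density
  estimation of f(o) followed by marginalisation) so users can check how far
  their data sits from the constant-prior assumption.  Note a structural
  fact: because f(any|d) = 1/2 identically, the marginal prior of the `any`
  component is exactly 1/2 whatever the data; only the rate components can
  approach 1/3 each.

Transitions use a single parameter: probability γ of staying in the current
state, with the remaining mass spread uniformly over the other 11 states.
γ > 1/12 penalises switching and acts as implicit temporal smoothing;
γ = 1/12 makes adjacent samples independent.  The initial state is uniform.
Decoding maximises the joint path weight with the Viterbi algorithm.

## Parameters

| name | unit | default | role |
|---|---|---|---|
| mu_d | mm | 2.5 | dilation (d − min_d) separating occluded from distended |
| sigma_d | mm | 0.4 | softness of the occluded/distended threshold |
| sigma_ddot | mm/s | 0.4 | width of the quiet band for ḋ |
| sigma_pdot | mmHg/s | 3.0 | width of the quiet band for ṗ |
| gamma | — | 0.5 | self-transition probability (smoothing) |
| dt | s | 0.25 | sampling interval of the aligned grid |
| min_d | mm | data-derived | diameter floor; per-chain minimum unless overridden |

All are hand-tuned constants, not fitted quantities (there is deliberately
no Baum–Welch/EM path).  γ is sampling-rate dependent: at a different dt it
should be re-tuned by the user; the package performs no automatic rescaling.
min_d is resolved per sensor chain (each chain is an independent model; its
occlusion floor is its own recorded minimum).  A global override
(`ModelParams(min_d=...)`) is available for users who prefer a single floor.

## Numerical choices

* All decoding runs in log space; log Φ uses `scipy.special.log_ndtr`, which
  stays finite far into the lower tail, so extreme observations (or the
  near-degenerate σ values visited by the sensitivity sweep) never produce
  NaNs.
* Ties in the Viterbi maximisation are broken towards the lowest canonical
  state index (the order oimc, oimr, dipi, dipd, itc, itr, atc, atr, ps, pd,
  oq, dq), consistently in the per-step maximisation and the backtrace.
  Ties have measure zero for real-valued observations but a fixed rule makes
  the decoder fully deterministic and makes the "switch count is
  non-increasing in γ" property well-defined.
* Non-finite observations are rejected with the offending sample index;
  imputation is a preprocessing concern, not a decoding one.
* The sensitivity sweep uses 16 evenly spaced values per analysis range
  (μ_d 0–7.5 mm, σ_d and σ_ḋ 0–1.2, σ_ṗ 0–9, γ 0.255–0.99); all five
  reference values fall exactly on these grids.  Range endpoints outside the
  open parameter domain (σ = 0; γ ∈ {0, 1}) are clamped inward by 1e-6, and
  grid values within numerical noise of the reference snap to it exactly so
  ε(reference) ≡ 0.  min_d is data-derived, identical in every re-decode,
  and is not swept.

## Preprocessing

Pressure baseline drift is removed with an iterated Gaussian-minima lower
envelope: starting from b = p, iterate b ← min(b, smooth(b)) with a Gaussian
kernel (default width 10 s — longer than a phasic peak, shorter than drift —
and 100 iterations).  Smoothing pads both ends by linear extrapolation of
the locally fitted slope; with constant or reflected padding the envelope
erodes without bound at the ends of a trending record, whereas
linear-extrapolation padding is exact for linear trends and makes the
operation idempotent to machine precision.  The subtraction maps the local
resting pressure to zero, which is immaterial downstream: decoding uses only
the pressure *rate*.

Diameter and pressure maps recorded at different resolutions and offsets are
combined by binning both onto one target grid: the coarsest time and space
resolution of the two inputs (overridable), shifted by user-supplied
temporal/spatial offsets (synchronisation is hardware-specific and outside
this package's scope).  Cells are half-open intervals labelled by their
lower edge; each cell takes the arithmetic mean of the source samples inside
it (these are intensive quantities, so means, not sums); empty cells are
filled from the nearest filled cell in time, and entirely empty sensor rows
from the nearest filled row.  Both outputs share identical coordinate
arrays, so observation vectors are assembled with no interpolation.

## Synthetic data

There is no public co-registered diameter/pressure data set, so the
generator inverts the emission semantics: a Markov chain with self-transition
probability `gamma_true` drives per-sample rate draws — quiet components give
zero-mean normal noise, pos/neg components half-normal magnitudes with a
single scale knob (sign-correct by construction) — which are integrated into
diameter and pressure traces, clipped to physical bands, plus measurement
noise.

States and traces are sampled *jointly*: at each step the transition
distribution is restricted (by rejection, implemented as renormalisation) to
states admissible at the current noise-free diameter and pressure —
occluded-component states only within 10% of the diameter range above the
floor, distended states only above 40% dilation, and moving components only
with ≥3% of the respective range of travel left before a clip bound.
Without the gate, truth labels contradict the rendered traces (an "occluded"
truth sample with a distended diameter) and recovery accuracy is
meaningless; gating on the actually-rendered traces rather than a surrogate
path is what makes the labels coherent.

Default study conditions: 5 sensors × 2400 samples (10 min at 4 Hz),
diameter band 4–14 mm, `gamma_true` = 0.98 (mean dwell ≈ 12.5 s), active
speeds 1.5 mm/s and 8 mmHg/s against quiet noise 0.1 mm/s and 0.8 mmHg/s,
measurement noise 0.05 mm and 0.2 mmHg, resting pressure 10 mmHg in a
0–60 mmHg band, plus a slow sinusoidal pressure drift (3 mmHg over 120 s) so
baseline removal has work to do.

What the generator does *not* emulate: real colon biomechanics (wall
tension, propagating neural waves, flow coupling between neighbouring
sensors — chains are spatially independent), video artefacts, or sensor
dropout.  Passing recovery tests therefore demonstrates that the decoder
inverts its own observation model under realistic noise and dwell
statistics, not that it is validated on tissue.

## Evaluation

For comparisons the twelve states collapse to three classes: active
contraction ac = {oimc, itc, atc}, active relaxation ar = {itr, atr}, and a
passive class holding the other seven states.  The passive class is called
`pas` here because the field's customary abbreviation collides with the
state label ps (passive shortening).  The classification error ε between a
reference and a comparison decoding is the fraction of samples *active in
both* whose active class differs; it is symmetric, lies in [0, 1], and is
undefined (a raised error, never a silent NaN) when no sample is active in
both.  Transition-occurrence matrices count ordered state pairs within each
sensor row; rows are never concatenated across sensors.

## Problem sizes in the test suite

Exhaustive Viterbi oracles enumerate all 12^N paths for N ≤ 5 over 100
random sequences; recovery experiments use the default 5 × 2400 conditions
over 10 seeds; the sensitivity suite sweeps 5 parameters × 16 values on one
default recording.  These sizes keep the whole suite under a minute while
leaving every assertion at full strength.

## Known limitations

* The emission weight is not a normalised density over observations (a
  documented consequence of the constant-prior approximation); absolute path
  scores are comparable only between decodings of the same data.
* Transition probabilities are state-independent by design; physically
  implausible jumps are discouraged only by the data, not by the model.
  Empirically (and in the synthetic checks) such jumps — e.g. occluded
  quiescence directly to a distended pressure rise — do not occur in decoded
  maps at realistic noise.
* γ must be re-tuned when the sampling rate changes.
* Only the Viterbi point estimate is produced; no posterior marginals or
  uncertainty per sample.
* The alignment offsets between the two recording modalities must be
  supplied by the user.
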