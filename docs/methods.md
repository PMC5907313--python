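# Methods

## Normalized network model

A model document lists species (with compartment and role), reactions,
branch points, regulatory edges, flux sources, hormone profiles and receptor
pairs. Compilation solves the nominal fluxes v⁰ⱼ from linear flux balance at
the all-ones state: one unknown total outflow per branch point (members tied
to it by their fractions) plus one flux per non-branch reaction, solved by
least squares and accepted only if every dynamic species balances to ≤ 1e−9
and every flux is strictly positive ("normalizable"). Zero-order synthesis
(regulator, transcript and cholesterol production, insulin secretion) is
expressed as flux sources rather than substrate-less reactions because a pure
synthesis/degradation loop has no flux-balance scale of its own; a source
pins the turnover rate.

The rate law is normalized multiplicative mass action,
v = (f/f⁰)·v⁰·∏xₛ^n·∏g(x), with linear activator g = 1+w(x−1) and hyperbolic
inhibitor g = 1/(1+w(x−1)), both equal to 1 at the nominal state so that
regulation is neutral there by construction. g is clipped to
[1e−6, 1e6]; inhibitor weights in the shipped network stay below 1 so the
clip region is never entered in practice. This functional form is the
package's own convention: it reproduces the two properties the framework
requires — the all-ones state is a steady state, and branch fractions are the
governing flux-distribution parameters — with a single weight per edge.

Normalization is anchored at the *basal* source rates. Diet and challenge
multipliers act after normalization, so a western diet genuinely displaces
the system from the all-ones state instead of being absorbed into it.

Perturbing one branch fraction rescales its siblings proportionally so the
branch still sums to 1: a fraction is a flux *distribution* parameter, and
proportional rescale is the unique choice that preserves total outflow.
Fractions ≤ 1e−9 are rejected at validation because the control-coefficient
quotient divides by fraction differences.

## Hormonal layer and sexes

Hormones are grouped into growth hormone, androgens and estrogens, each with
its own source. Waveforms are mean-preserving: a raised cosine for the male
daily growth-hormone oscillator (period 24 h, amplitude 0.8 of mean) and a
von-Mises-shaped bump (κ = 4, exact unit mean by construction of
e^{κcosθ}/I₀(κ)) for the female estrous estrogen cycle (period 720 h,
amplitude 0.9, peak mid-cycle), chosen as the simplest smooth, non-negative,
single-peaked shapes with the documented periods. Source-strength ratios are
androgen:estrogen = 10 in males and estrogen:androgen = 3 in females, with
the larger sex-hormone mean normalized to 1 and growth hormone at mean 1 in
both sexes.

Receptors use quasi-steady-state saturable binding: active = total·H/(K+H)
(default K = 1, total = 1), with active + inactive conserved exactly. In the
compiled model the receptor species carry the *normalized* forms (value 1 at
nominal hormone level) so that receptor-driven regulatory edges are neutral
at the nominal state like every other edge. Females additionally carry a
negative estrogen-receptor edge (weight 0.5) on the growth-hormone source.

Because every oscillation is mean-preserving and each sex is normalized to
its own all-ones steady state, period-averaged behaviour would differ between
sexes only through weak nonlinear rectification of the forcing. The
substantive sex dimorphism is therefore carried by explicitly sex-dependent
regulatory-edge weights installed by the sex configuration — the documented,
configurable surrogate for receptor→liver wiring that is not reducible from
first principles at this model scale. A custom `SexConfiguration` bypasses
the per-sex invariants deliberately (e.g. receptor-dysfunction or
symmetry-null experiments).

## Steady states

Under oscillatory forcing the reported steady state is the periodic steady
state, summarized as period averages over the longest active hormone period
(720 h for females, 24 h for males, 24 h fallback). Consecutive windows are
integrated (LSODA, rtol 1e−8/atol 1e−10, 181 samples per window, trapezoid
averaging — spectrally accurate for periodic signals) until the per-species
relative drift of the window average falls below rel_tol (1e−6 periodic,
1e−8 constant), with a 200-window cap that raises a diagnostic error.
Fully constant models are solved by a Newton root solve first (verified
against the RHS residual and non-negativity) with windowed integration as
fallback; for constant inputs the instantaneous and period-averaged states
coincide, which is tested. Averaging is the only sex-symmetric scalar
reduction of an oscillator-forced state, which is why period averages rather
than point readings are reported.

## Control-coefficient protocol

C = ((X*−X)/(f*−f))·(f/X) with one-sided increments f* = f(1+δ),
δ ∈ {5,10,15,20,25,30}%, after raising the triglyceride influx 10-fold.
Increments with f* ≥ 1 are skipped with a warning; a scan with no usable
increment is an error. The headline coefficient is the 5% value — the
smallest protocol increment and hence the closest to the derivative — with
the mean and the largest-magnitude increment stored alongside; this
aggregation is a declared convention. Classification as highly sensitive
uses |C| > 1 so that sign conventions (export branches of an accumulating
output have negative coefficients) cannot silently drop a reaction. All
rankings break ties lexicographically by parameter id. Per-parameter
perturbed steady states are cached and shared between the triglyceride
(CfTG) and regulator (CfR) analyses; perturbed solves start from the
challenged baseline to shorten transients.

On the toy hub-and-chains network these conventions give exactly +1
(same branch) and −f/(1−f) (cross branch) at *every* increment, which the
generator returns as the analytic oracle table; agreement to 1e−3 is the
correctness anchor of the pipeline.

## Reference network calibration

The packaged reference network is a reduced, calibrated surrogate, not a
reconstruction: it embeds the twenty named catalog branch reactions in
scaffolding stoichiometry (ids prefixed `s_`/`r_`; six catalog ids without a
published reading — k163, k144, k800, k102, k105, k176 — are carried as
scaffold branch arms and listed in `metadata.unmapped_ids`). Design choices
that make its sensitivity structure interpretable and robust:

- The observed output is a hepatic TG droplet pool fed by a dedicated
  storage arm (k176) of the liver-TG branch, with a weak self-inhibition
  (w = 0.05) representing saturating droplet growth.
- The glycerol/glucose and ketone axes are fed by diet-independent influxes
  (monoacylglycerol, blood fatty acid and ketogenic amino-acid sources), so
  their species sit at ≈1 even under the 10-fold triglyceride challenge and
  the regulation multipliers keep their full elasticity there.
- Sex-dependent weights: glycerol→storage activation 2.2 (male) / 4.4
  (female), ketone→storage activation 0.05 (male) / 1.65 (female), and
  sign-flipped lipid-load edges on the three marker transcripts. These four
  knobs produce the calibrated structure: k159 first in both sexes and in
  the sex-difference ranking, {k159,k177} vs {k159,k177,k152} threshold
  sets, identical top-5 k159 regulators, and inverse marker responses.
- Branch fractions were sized so that no scaffolding sibling of a
  highly-sensitive arm crosses |C| = 1 (a sibling of a branch with
  perturbed fraction f responds with −f/(1−f) times the branch gain, which
  bounds admissible fractions; the MAG branch therefore has five arms).

The asset is emitted deterministically by `scripts/build_reference.py` and
locked by a SHA-256 digest; builder, asset and digest are cross-checked in
the tests. Absolute coefficient magnitudes of a full-scale network are not
reproducible from a reduced surrogate and are not targeted — ranks,
threshold classifications and signs are.

## Problem sizes and runtime

The reference network has 66 species, 80 reactions, 29 sources and 15 branch
points (32 branch parameters). A full two-sex MCA scan (32 parameters × 6
increments, period-averaged solves with 720 h female windows) runs in about
two and a half minutes on one CPU; the examples restrict themselves to a few
parameters where full scans are not the point.

## Limitations

- The surrogate's regulatory wiring is qualitative: edge weights encode
  calibrated sensitivity structure, not measured affinities, and the
  sex-dependent weights stand in for unresolved receptor→liver mechanisms.
- Concentrations are normalized; outputs are fold changes over the healthy
  baseline, never absolute concentrations.
- Growth-hormone secretion is a smooth daily oscillator, not pulsatile
  episodic bursts; hormone pharmacokinetics are out of scope.
- The gene-expression tier is first-order transcript turnover; translation
  and post-translational regulation are lumped into the edge weights.
- Passing tests demonstrate internal consistency and the calibrated
  qualitative structure under the stated synthetic conditions; they do not
  validate the surrogate against new experimental data.
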