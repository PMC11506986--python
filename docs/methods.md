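# Methods

## Model and state space

`epime` treats the classical SIS and SIR compartmental models as
continuous-time Markov chains over population configurations rather than as
ODEs for mean occupations.  A closed, well-mixed population of N individuals
undergoes two reactions:

* contagion — a susceptible becomes infectious at total rate β·S·I/N
  (frequency-dependent contact);
* recovery — each infectious individual recovers at rate γ, returning to the
  susceptible pool (SIS) or moving to the removed pool (SIR).

The configuration is the infected count I for SIS (S = N − I) and the pair
(S, I) for SIR (R = N − S − I).  The probability vector P over
configurations obeys the master equation dP/dt = H·P, where H is the
transition-rate generator: entry (x′, x) is the rate of the single reaction
x → x′ and the diagonal closes each column to zero.  This matrix is the
occupation-number representation of the second-quantised (Doi–Peliti)
Hamiltonian of the process; the ladder and number operators are realised
only through the matrix elements they induce — no symbolic operator algebra
is performed.  The convention is columns-as-source states, so "every column
sums to zero" is the probability-conservation law; off-diagonal entries are
non-negative and columns of absorbing configurations (I = 0) vanish
identically.

SIR basis ordering is frozen for reproducible output: lexicographically
descending in S, ascending in I, with the closed-form index
idx(S, I) = (N−S)(N−S+1)/2 + I.  The SIS basis is indexed by I directly.
The state-space size is N+1 (SIS) or (N+1)(N+2)/2 (SIR); a guard (default
2×10⁵ states) rejects dimensions whose propagators would not fit in memory
comfortably, since SIR storage grows quadratically with N.

## Propagation

The formal solution P(t) = expm(Ht)·P(0) is evaluated over discrete steps of
fixed length Δt (default 0.1 time units) by repeated application of the
single-step propagator expm(HΔt), computed once per run.  Two routes
implement the exponential action:

* dimension ≤ 2000 — the dense propagator matrix is formed once by
  scaling-and-squaring; each step is a mat-vec;
* larger systems — the exponential acts matrix-free on the vector
  (`scipy.sparse.linalg.expm_multiply` on the precomputed sparse HΔt).

Both routes agree to better than 1e−8 on overlapping sizes (tested), and the
propagation is checked against an independent Taylor
scaling-and-squaring exponential in the unit tests.  Floating-point
exponential action can produce harmless tiny negatives: entries in
[−1e−12, 0) are clipped to zero and the vector renormalised; anything more
negative, or a mass defect beyond 1e−8 per step, raises a propagation error
(it indicates a broken generator, not roundoff).  Mass conservation is
re-checked at every recorded snapshot at 1e−9.

Long absorbing runs support early stopping: the propagation ends when the
max-norm change of the state per unit time drops below 1e−8, checked every
10 recorded snapshots.  Time horizons then act as upper bounds.

## Deterministic baselines

The SIS mean-field equation dρ/dt = (β−γ)ρ − βρ² is solved in closed form
(logistic), written with e^{−rt} on the growing branch so horizons of
thousands of time units do not overflow; β = 0 and R0 = 1 use their
respective exponential and algebraic limits.  The SIR system is integrated
with DOP853 at rtol 1e−10.  The final epidemic size solves
ρ = 1 − s₀e^{−R₀ρ} − r₀ by Brent bracketing on [1e−9, 1] to 1e−12; when no
positive root exists (R₀s₀ ≤ 1 with vanishing initial infection) the
disease-free root 0 is returned.  Peak location uses a 0.01 grid with
earliest tie-break; a maximum that does not strictly exceed both endpoint
values (monotone decay, or the SIS rise to a plateau) is flagged as
"no interior peak" rather than raising.

## Observables

Marginals P(I) = Σ_S P(S,I) and P(R) = Σ_{S+I=N−R} P(S,I) are bincount
reductions over the basis.  Uncertainty is the Shannon entropy
H = −Σ P log P with natural log by default (configurable base; all
qualitative conclusions are base-invariant) and the 0·log 0 = 0 convention.
The no-outbreak mass integrates the stationary recovered marginal up to the
minor-outbreak bound (below).  Order-parameter clouds scan R0 at fixed
γ = 0.1 with β = γR0; the SIS marginal is measured at t = 1000 — late enough
for the metastable structure, before full absorption dominates at moderate
N — while the SIR marginal is taken at stationarity (early-stopped).

## Extinction probabilities

Early in an outbreak, contagion (rate βS₀I₀/N ≈ βI₀ for S₀ ≈ N) and
recovery (γI₀) compete, giving the linear extinction recursion
π(I₀) = R₀/(R₀+1)·π(I₀+1) + 1/(R₀+1)·π(I₀−1) with π(0) = 1.  Its bounded
solution is the threshold law: π = 1 for R₀ ≤ 1 and (1/R₀)^{I₀} above
threshold (independent initial lineages).  At R₀ = 1 exactly, 1 is returned
(the branches meet continuously).  The recursion solver truncates at
i_max = 200 by default with π(i_max) = 0 above threshold (truncation error
O(R₀^{−i_max})); for R₀ ≤ 1 both boundaries are 1 and the solution is
identically 1, returned exactly.  A consistency report verifies that the
competing rates equal the SIR generator matrix elements; the branching
picture permits S₀ = N alongside I₀ ≥ 1, which has no representable basis
state, so that comparison is made at the nearest configuration (N−I₀, I₀).

## Stochastic simulation and minor outbreaks

The τ-leap simulator draws Poisson event counts per leap (means βSIτ/N and
γIτ), capped at the available individuals with recovery applied after
contagion within a leap; the cap biases large-τ runs, so the exact
event-driven simulator (direct-method sampling of individual reactions) is
the arbiter.  Measured against it at N = 500, R0 = 2, the leaping bias for
τ ≤ 0.2 is already below Monte Carlo resolution at desk-scale ensemble
sizes; the default τ = 0.05 is comfortably inside that regime.  Runs are
seeded by (base_seed, run_index) so ensembles are reproducible and
embarrassingly parallel.

A trajectory is a minor outbreak when its final attack count is at most
0.2·R∞_det + I₀ for R₀ > 1 (R∞_det the deterministic attack count from the
final-size relation) and 0.2·N + I₀ for R₀ ≤ 1, where no major outbreak
exists.  The 0.2 multiplier is a convention: the attack-rate distribution is
strongly bimodal, so classified fractions move by less than 0.02 when the
multiplier is dropped to 0.05 (tested).  Headline ensemble comparisons use
N = 10⁴ with n = 1000 runs per parameter point; larger populations sharpen
the minor/major separation but do not change the fractions materially.

## Forecast-uncertainty study

A deterministic SIR trajectory (γ = 0.1, β = γR₀, I₀ = 1) serves as the
observed course of an outbreak.  Conditioning at time t₀ collapses the
probabilistic state onto the configuration nearest the observed fractions —
nearest-integer rounding of s·N and i·N, decrementing S (then I) if rounding
pushes S + I past N.  A point mass (not a spread) is used: observation plays
the role of a measurement that leaves the system in a definite
configuration.  The conditioned state is propagated to twice the reference
peak time, recording the infected-marginal entropy at every step; reported
are the entropy at the reference peak, H_inf(t_peak), and the location of
the entropy maximum t_Hmax (earliest argmax over [t₀, 2t_peak]).  Times are
standardised as Δt̃₀ = (t₀ − t_peak)/t_peak ∈ [−1, 0] and
Δt̃_Hmax = (t_Hmax − t_peak)/t_peak.  The default study covers
R₀ ∈ {2, 4, 6} at N = 100 over a 21-point conditioning grid — a desk-scale
setting that resolves the full qualitative structure.

A caveat the tests make explicit: at N = 100 the integer conditioning
quantises the initial state, so adjacent conditioning times can map to the
same configuration (shifting t_Hmax forward) or jump the rounded infected
count by one (shrinking the extinction atom and pulling the entropy maximum
earlier).  The resulting ±0.05 jitter in Δt̃_Hmax at early conditioning
times is intrinsic to point-mass conditioning at this population size; the
delayed-maximum trend is monotone on the late half of the grid and in the
large-N limit, and the property tests assert it there.

## Synthetic data and what the tests show

The package needs no external data; every test input is generated by the
code itself.  Reference conditions mirror the framework's standard setting:
rates β = 0.6, γ = 0.1 (R0 = 6) with Δt = 0.1, SIS populations up to 1000
and SIR populations of about 100 (the state space is the binding
constraint), R0 scans over [0.8, 4] and ensembles of n = 1000 runs.  Small
analytic systems — the N = 1 pure-death chain (survival e^{−γt}), the N = 2
no-transmission chain (binomial recovery marginals) and the N ≤ 6
enumerated-transition tables — anchor the propagation and generator code to
closed forms.  These synthetic settings exercise well-mixed, constant-rate
dynamics only: agreement there validates the numerics, not the realism of
mean-field SIS/SIR for any particular pathogen (no contact structure,
demography, or time-varying rates).

## Numerical conventions, in brief

Generator column sums vanish to 1e−12.  Propagation conserves mass to 1e−9
per snapshot; semigroup consistency holds to 1e−8.  Entropies are clamped
at 0 from below against −0.0.  Argmax ties break earliest everywhere.
Fractional no-outbreak bounds include the floor of the bound.  Wilson
intervals (z = 1.96) summarise binomial ensemble fractions.

## Known limitations

Well-mixed homogeneous populations only; no networks, metapopulations or
demography.  SIR state spaces grow as N²/2, capping exact propagation near
N ≈ 600 under the default guard.  The τ-leap clipping policy biases results
for τ well above the default.  Point-mass conditioning quantises forecast
studies at small N as described above.
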