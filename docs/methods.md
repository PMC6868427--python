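# Methods

## Two-site longitudinal exchange model

For a molecule exchanging between folds A and B slowly enough that each fold
gives a resolved resonance, z-magnetization during a mixing period obeys
dM/dt = −A·M with A = [[k_f+R1_A, −k_b], [−k_f, k_b+R1_B]]. Writing
a11 = k_f+R1_A, a22 = k_b+R1_B, a12 = −k_b, a21 = −k_f, the eigenvalues of
−A are λ₁,₂ = ½[−(a11+a22) ± √((a11−a22)² + 4a12a21)] (λ₁ ≥ λ₂, both ≤ 0).
Sylvester's formula gives the ZZ auto-peak decays as the diagonal elements
of exp(−At):

    M_AA(t)/M_AA(0) = [(a22+λ₁)e^{λ₁t} − (a22+λ₂)e^{λ₂t}] / (λ₁−λ₂)
    M_BB(t)/M_BB(0) = [(a11+λ₁)e^{λ₁t} − (a11+λ₂)e^{λ₂t}] / (λ₁−λ₂)

T1-experiment decays propagate the equilibrium vector (p_A, p_B) =
(k_b, k_f)/k_ex and normalize each component by its own zero-time value;
with detailed balance this collapses to the same biexponential with
prefactors (a22−a21+λᵢ) for channel A and (a11−a12+λᵢ) for channel B. The
equilibrium-weighted initial condition is adopted as the model contract: it
is the unique initial condition under which those prefactors are exact.

All closed forms are validated against a generic `scipy.linalg.expm`
propagator (the implementation-independent oracle) to <1e−9 over 1000 random
parameter sets per test run. At t = 0 every curve is exactly 1 by
construction. When |λ₁−λ₂| < 1e−10 s⁻¹ (only possible when k_f·k_b = 0 and
a11 = a22) the limiting form e^{λt}(1 + (c+λ)t) replaces the 0/0 quotient.

### Joint fitting

All channels of one residue (at minimum AA+BB; ideally AA, BB, A, B) are fit
jointly with the four shared parameters via bounded trust-region least
squares (`scipy.optimize.least_squares`, all parameters ≥ 0, xtol/ftol
1e−12). Residuals are weighted 1/σ when per-point errors are supplied.
Initialization exploits two exact small-t identities: the initial slope of a
T1 channel is −R1 of that fold, and of a ZZ auto-peak is −(k+R1), so
log-linear fits of the first five points seed all four parameters; on
failure up to five deterministic rescaled restarts are tried.
Non-convergence raises an error carrying the best-so-far parameters and
solver diagnostics.

### Monte-Carlo uncertainties

Parametric bootstrap: synthetic datasets are drawn from the best-fit curves
plus i.i.d. Gaussian noise (sd defaulting to the *unweighted* residual sd of
the fit), refit starting from the best-fit vector, and per-parameter sds
taken across runs; a run count and seed are recorded in the result. More
than 20% failed refits aborts with diagnostics. The reference protocol uses
1000 runs; the test suite uses 60–300 to stay inside its time budget, which
changes the sd estimate only at the ~few-percent level (relative error of an
sd from n draws ≈ 1/√(2n)). A coverage test checks that ±1 sd intervals
cover the generating k_ex in 60–75% of 200 simulated experiments.

## Sugar pucker from quantitative J

The cross/diagonal ratio of the H1′(C1′)H2′ experiment follows
S_cross/S_diag = −tan²(2πJζ) with ζ = 13.05 ms by default; J is recovered on
the principal arctangent branch, valid for J < 1/(4ζ) ≈ 19.157 Hz. The
south (C2′-endo) fraction is the linear interpolation of J between limiting
couplings of the pure conformers. The defaults j_north = 1.0 Hz and
j_south = 8.8 Hz are *calibration choices of this package*, not literature
constants: 8.8 Hz is the measured coupling of a tetraloop uridine known to
be predominantly C2′-endo (a common internal standard), and 1.0 Hz is a
typical pure-north value; both are configurable. An absent cross peak is
reported as pure C3′-endo with J undefined — at ζ = 13.05 ms the detection
threshold |ratio| < 0.01 corresponds to J ≲ 1.2 Hz, so non-detection is a
noise-floor statement, not J = 0.

## Fold populations

In slow exchange, fold populations are volume ratios: p_1B = V_1B/(V_1B+V_2B),
with first-order error propagation. Overlapped 1D resonances are decomposed
by a two-Lorentzian fit I(x) = Σ Aᵢ/(1+((x−x₀ᵢ)/(wᵢ/2))²) + c with a
constant baseline co-fitted (a linear baseline was considered and rejected
as unidentifiable on narrow windows); analytic areas Aᵢπwᵢ/2 feed the
population estimate. Fits whose positions end up closer than max(w)/4 are
flagged merged and their individual areas should not be trusted. Titration
series report the direction of p_2B change along the given condition order.

## Melting thermodynamics

Absorbance melts are reduced to the association degree with sloped linear
baselines fitted in two windows (defaults: the lowest/highest 15% of the
temperature range): α(T) = (A_high(T) − A(T))/(A_high(T) − A_low(T)),
clipped to [−0.05, 1.05] with a warning. α is then fit to the two-state
van't Hoff form α = 1/(1+exp((ΔH°−TΔS°)/RT)) (R = 8.314 J mol⁻¹ K⁻¹; ΔH° in
kJ/mol), initialized from the 0.5-crossing and the mid-transition slope
(dα/dT at Tm = ΔH/(4RTm²)). Tm = ΔH°/ΔS° and α(Tm) = ½ are identities of
the fitted model. Errors come from seeded residual-resampling bootstrap;
cycle averaging reports mean ± sd of Tm and excludes (with a warning)
cycles that fail.

**Known bias.** Window-based baselining assumes the windows sample pure
baseline. When the transition tail reaches into the high-T window (Tm
within ~6 decay constants RT²/|ΔH| of the range top), the extrapolated
unfolded baseline is skewed and |ΔH| is overestimated by a few percent
(≈3% for ΔH = −200 kJ/mol, Tm = 333 K on a 288–368 K scan). The tests
document this regime explicitly and validate accuracy (<1%) only where the
precondition holds. Global baseline+transition fitting would remove the
bias but is out of scope.

## Synthetic-data generator

The generator emulates the reduced observables, not raw spectra: decay
curves are the closed forms at the standard eleven mixing times (5, 10,
20, …, 100 ms) plus i.i.d. Gaussian noise of sd 1/SNR (default SNR 100, a
typical well-set-up 2D intensity measurement); peak volumes are lognormal
around p·V_total with CV 5% (mean-preserving parameterization); traces are
two Lorentzians (separation ≈10 FWHM) with 1% additive noise; couplings
follow the forward tangent law; melts are the α model between sloped
baselines with 0.002 AU noise, five cycles alternating 250/260 nm. Preset
rate constants derive from published k_ex values (20.89, 15.24, 10.11,
7.88 s⁻¹) split by detailed balance at the 60/40 apo populations; R1
defaults to 2.5 s⁻¹ (typical ribose C1′ at 14.1 T) since fitted R1 values
are not published. What a green recovery test establishes is therefore
*self-consistency of the estimators at realistic noise*, not agreement with
the original raw data (which are not deposited); it does not probe peak
overlap, baseline distortions, or temperature instability in real spectra.

## Numerical conventions

Rates s⁻¹, times seconds internally (ms at the CSV boundary), temperatures
Kelvin internally (°C at the boundary), energies kJ. Populations are
reported as (p_1B, 1 − p_1B) so the pair sums to 1 exactly in floating
point. All stochastic procedures take explicit integer seeds and are
reproducible bit-for-bit; generator streams are derived as
`default_rng([seed, stream_index])` so the per-table streams are independent
but jointly determined by one seed.
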