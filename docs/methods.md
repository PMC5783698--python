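# Methods

## Model and forcing

The package simulates a five-variable negative-feedback model of NF-κB
signalling: nuclear NF-κB (`Nn`) imports when free of IκB, activates IκB
transcription (`Im`, with quadratic dependence on `Nn`), translated IκB
(`I`) exports NF-κB, and TNF acts through an IKK activation/inactivation/
recycling cycle (`IKKa`, `IKKi`, with a neutral pool `IKKtot − IKKa −
IKKi`). A20 accelerates the TNF-dependence of IKK recycling. All 15
constants default to the published table (`default_parameters()`); total
NF-κB (1 μM) and total IKK (2 μM) are conserved by construction. Two
printed unit ambiguities are resolved by dimensional analysis: `kt` and
`alpha` must be μM⁻¹·min⁻¹ for the mRNA-production and IκB-degradation
terms to balance, and the export-rate symbol in the first equation is the
table's `kIin`.

TNF forcing is a square wave. The published description fixes only period
and amplitude, so the waveform convention is ours: symmetric about baseline
1.0 (value 1 + A for the first half-cycle, max(1 − A, 0) for the second,
50% duty), all three parameters overridable. Constant TNF = 1 is the
free-running reference. The alternative convention (switching between 0 and
a peak value) is supported through `baseline = amplitude`.

## Deterministic engine

Classic fixed-step RK4 (`dt = 0.01` min by default, recorded every 1 min),
with the forcing evaluated at sub-stage times and no event location at the
square-wave edges — the O(dt) edge error is far below every analysed
quantity, and convergence is verified in the tests against both a
half-step run (< 1e−6 relative at t = 1000 min) and an independent stiff
integrator (LSODA at rtol 1e−11). Identical inputs reproduce trajectories
bit-for-bit. Default initial condition: resting cell (0, 0, 0.5, 0, 0) μM;
initial-condition sweeps draw uniformly from the admissible box, with the
unbounded `Im` and `I` axes capped at 6 μM and 1.5 μM — the ranges the
attractors actually visit.

**Slow relaxation.** The model's limit cycles attract very slowly: from a
resting start the inter-peak interval decays from ~125 min toward the
asymptotic 83.6 min over roughly ten thousand minutes. Any "measured
period" over a finite window therefore depends on how much relaxation the
window contains: the conventional 3000-min window with 500-min discard
yields ≈ 109 min, while the attractor itself runs at 83.6 min
(`analysis/01_free_running_period.py` tabulates this). The experimentally
reported 90–100 min natural period falls between these; this package
reports what the stated computation produces and documents the
window-dependence rather than selecting a window to match.

## Stochastic engine

Exact Gillespie SSA with concentrations converted to counts via
f = N_A·V·10⁻⁶ molecules/μM. Default channel mapping is one channel per
ODE term (10 channels), each changing one species by ±1 with propensity =
deterministic term rate at the current concentrations × f. Nonlinear terms
(the Nn² and Hill-type factors) are evaluated directly at concentrations —
no n(n−1) combinatorial correction — so the SSA shares the ODE's mean rates
by design; the difference is O(1/f). This mapping splits the IKKa→IKKi
conversion term into two independent unary channels, which conserves the
IKK pool only in expectation; guard propensities zero any channel whose
reactant is exhausted or whose conserved pool (Nn ≤ Ntot·f, IKKa + IKKi ≤
IKKtot·f) is saturated, so counts never go negative and pool bounds hold
exactly. A `physical` mode (9 channels, fused conversion) is available
when strict IKK conservation is wanted.

Time-varying forcing: the square wave is piecewise constant, so
exponential waiting times are valid per segment. If a drawn event would
cross the next TNF switching time, the clock advances to the switch and
the waiting time is redrawn with updated propensities — exact for
piecewise-constant propensities. Recording is sample-and-hold on a uniform
grid. The generator is numba's seeded per-process RNG; the seed is recorded
in the trajectory metadata and identical seeds reproduce event sequences
exactly. Initial counts round half-to-even.

## Trace analysis

The pipeline mirrors the experimental quantification: moving-average
smoothing (default window 5 samples), strict local maxima, a height filter
at 10% of the smoothed trace's range above its floor, and a minimum peak
separation (default 20 min) that keeps the higher of two close peaks.
Measuring the threshold from the trace floor (rather than from zero) makes
detection invariant under affine rescaling of intensities, which is the
property that matters for ratiometric microscopy signals; for
near-zero-baseline traces the two conventions coincide. Simulated traces
are analysed at the 5-min imaging cadence (`record_every=5`); deterministic
traces need no smoothing (`smooth_window=1`).

Each inter-peak interval p is labelled with the allowed period ratio
r = p/T nearest in relative terms, if within tolerance (default 20%), else
"unentrained". The default ratio set {1/3, 1/2, 1, 2, 3, 4} separates the
observed tongues with margin; both set and tolerance are configurable.
Occupancy counts all intervals (summing to 1); a *transition* is a label
change between adjacent entrained intervals — unentrained intervals break
dwell runs but are never themselves counted as hops, so detection noise
does not inflate hop rates; rates are normalised per 1000 oscillations.
The transition heatmap conditions next-mode on current-mode over adjacent
entrained pairs, rows normalised.

## Tongues, multistability, chaos

A grid cell (T, A) is classified by integrating past the transient
(default 10,000 min — generous because of the slow relaxation noted above;
a shorter transient misclassifies the drifting quasi-periodic orbit near
the free-running period as 1/2-locked at weak 180-min forcing) and testing
two conditions over a 40-cycle horizon: (i) the rotation number
(mean interval / T) equals a rational of denominator ≤ 4 within 2% — the
defining property of frequency locking, with the same 2% used for the 1:1
invariant — and (ii) ≥ 90% of intervals classify to that rational. The
second condition alone is insufficient (quasi-periodic orbits drift within
snapping tolerance of a ratio); the first alone would accept a chaotic
window that happens to average near a rational. Denominators up to 4 admit
genuine higher-order lockings: at (50 min, 0.1) the model is bistable
between a 2:1 state (period 100 min) and a 7:4 state (period-4 interval
pattern 91/89/83/87 min), with basins ≈ 93%/7% over the sampling box — a
fixed seed is used where a 20-draw scan must find the minority basin. At
amplitudes 0.15–0.25 the 2:1/3:1 pair coexists (basins ≈ 3:1).

The largest Lyapunov exponent uses the two-trajectory Benettin method:
reference plus copy perturbed by δ₀ (default one molecule at the 1-fL
reference volume, ≈ 1/602 μM), renormalised every τ = 10 min, exponent =
mean ln-growth/τ with a standard error over blocks. A cell is flagged
chaotic when λ > 10⁻³ min⁻¹ with the 2-SE interval excluding zero; at
desk-scale run lengths this separates the strongly positive chaotic
exponents (≈ +0.01 min⁻¹ at T = 50, A = 0.8) from the near-zero values of
quasi-periodic cells. Locked cells give small negative exponents (the
attraction is slow, so λ ≈ −10⁻³ min⁻¹ with comparable SE; only the sign
is asserted). Period-doubling classifies the peak-height sequence by the
smallest k ∈ {1, 2, 4} that repeats within 5% relative tolerance; the
1:2-locked orbit at (180 min, 0.15) shows a clean order-2 alternation
(heights 0.180/0.204 μM).

## Multiplexing

Gene i follows dm/dt = γ Nʰ/(Kʰ + Nʰ) − δm, dP/dt = Γm − ΔP with the
published table (K = 1 for both genes, h = 2 vs 4). The μM-scale NF-κB
trace must be mapped onto the gene model's #molecules scale; the source
leaves this conversion unstated. The default normalises the input trace's
*maximum* to K, so oscillation peaks sit at the Hill half-saturation point
— the regime where the two promoters discriminate between modes. (An
alternative of normalising the time-average to K was rejected: it pushes
both modes' spikes deep into saturation for both genes, and expression
then tracks time-above-K, inverting the amplitude effect.) When comparing
modes of one cell, a single shared factor (K over the largest mode's
maximum) is applied to all traces so amplitude differences survive. Under
the coexisting 2:1 / 3:1 states at (50 min, 0.2) this yields gene-2
expression ≈ 1.4× higher in the larger-amplitude 3:1 ("1/3 tongue") state
with gene 1 within ≈ 17% — hopping between modes switches gene 2 while
gene 1 stays on. Integration is RK4 with the NF-κB input pre-sampled at
half-steps; constant inputs reproduce the closed-form steady state
(γ/δ)·Nʰ/(Kʰ+Nʰ)·(Γ/Δ) to better than 0.1%.

## Synthetic traces

The generator emulates the measured single-cell phenomenology — 5-min
sampling, spiky cycles entrained at rational multiples of a known TNF
period, dwell times of several cycles, mode-dependent amplitudes,
multiplicative then additive Gaussian noise (clipped at zero) — with
per-interval ground truth. Mode paths are first-order Markov chains
(stay probability 0.85 by default → geometric dwells of mean ≈ 6.7
cycles over the 1:2/1:1 mode pair at T = 180 min). Each interval
contributes one raised-cosine spike sharpened by an exponent (default 5,
half-width ≈ 0.19 of the cycle); cycles peak at their boundaries, so
inter-peak intervals equal cycle periods exactly and ground truth aligns
with how the analysis labels data. Half-cycle flanks pad both ends so
every true peak is an interior sample. Per-mode amplitude defaults to
√(r/r_max) — higher-frequency modes peak lower. The spike sharpness was
chosen so the noiseless trace survives the default smoothing/detection
pipeline without boundary-peak shifts, making zero-noise recovery exact;
benchmark accuracy is matched by interval midpoints, degrades gracefully
with noise (≈ 0.97 at 40% multiplicative noise, ≈ 0.84 at 80%) and is
reported with seed provenance.

What the generator does *not* emulate: imaging artifacts, tracking errors,
cell division, bleaching, cell-to-cell parameter variability, or the
waveform asymmetries of real NF-κB spikes. Passing recovery benchmarks
therefore validate the pipeline's logic and noise robustness, not its
performance on every pathology of real microscopy data.

## Problem sizes and numerical conventions

Default problem sizes keep every analysis on one CPU core in minutes:
tongue scans use a 24 × 13 grid at dt = 0.02 with 30-cycle horizons;
hop-rate sweeps use runs of ~200–300 oscillations at 3 seeds × 4 volumes;
chaotic period statistics use 1000-oscillation runs; the Lyapunov
diagnostics use 400–2000 renormalisation blocks. Ties in peak heights are
broken by scipy's peak selection (first-come within `distance` pruning);
degenerate inputs (constant traces, empty interval lists, single-mode
heatmaps) return empty or trivial structures rather than raising, except
where a minimum data requirement is documented (≥ 8 peaks for
period-doubling, ≥ 2 entrained adjacent intervals for heatmaps).
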