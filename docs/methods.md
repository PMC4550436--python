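# Methods

## The model

A single output neuron receives feedforward synapses, with strengths
`w(x) ∈ [0, 1]`, from a 1D chain or 2D lattice of input neurons. Traveling
wavefronts of activity sweep the input layer at speed `v`; each recruited
input fires a burst (boxcar rate profile, `R_in = 50` Hz for duration `d`,
Bernoulli spikes on a 1 ms clock), every input spike deposits a
weight-scaled EPSP (unit-integral difference of exponentials,
`τ_d = 5` ms, `τ_r = 1` ms) on the output neuron, and the output fires
either as a linear-Poisson unit (rate ∝ summed EPSPs) or as a leaky
integrate-and-fire unit (absolute refractoriness 2 ms, relative 5 ms).
Every pairing of an input and an output spike within `5 τ₋` modifies the
synapse by `η K(Δt)` with `Δt = t_in − t_out`:

* asymmetric rule: `K = A₊ e^{Δt/τ₊}` for `Δt < 0`, `−A₋ e^{−Δt/τ₋}` for
  `Δt > 0`, `0` at coincidence (defaults `τ₋ = 2τ₊`, `A₊ = 1`, `A₋ = 0.51`);
* symmetric rule: difference of Gaussians with `τ₋ = 1.6 τ₊`, `A₊ = 3.2`,
  `A₋ = 2.1`.

Because a wave enforces a strict map between a neuron's position and its
firing time, the pairing rule acts as a *spatial* interaction between
synapses. Averaging over one wave passage gives the mean-field dynamics

    ∂_T w(x) = η (κ ∗ w)(x),
    κ(x) = K_v(x) ∗ α(−x/v) ∗ α(x/v) ∗ ε(x/v),   K_v(x) = K(x/v)/v,

where `α` and `ε` are the burst profile and EPSP mapped into space and act
as low-pass filters. In Fourier space each weight mode grows as
`exp(η Re[κ̃(k)] T)` once wave directions alternate (reversing `v`
conjugates the spectrum, cancelling the imaginary, phase-advecting part),
so an initially unstructured weight field develops a periodic pattern at
the dominant frequency `k* = argmax_{k>0} Re[κ̃(k)]` — a Turing-type
instability in which the narrow strengthening lobe plays the activator and
the wide weakening lobe the inhibitor. A receptive field is one cycle (a
contiguous block of strong synapses) of this pattern; whether an initial
RF of diameter `RF₀` expands, contracts, or splits is set by `1/k*`
relative to `RF₀`.

## Numerical construction of κ and its spectrum

`theory.build_kappa` samples `K_v` on a uniform grid (default 0.6 µm) over
`±max((5τ₋ + 2d)·v, 5 mm)` and convolves it (overlap-add) with the burst
and EPSP factors, each sampled on its own compact grid with 8-fold
sub-sample bin averaging (keeps the boxcar edges second-order accurate)
and normalized to unit integral — so the DC of κ equals `∫K dΔt` and all
purely positive rate prefactors (`R_in`, `R_out`) are absorbed into `η`.
At the jump of the asymmetric rule the `x = 0` sample takes the mean of
the one-sided limits, which makes grid sums converge to the true integral.

`theory.spectrum` block-averages the kernel to ≤ 2¹⁹ samples (κ is smooth
on that scale and its spectrum lives at low `k`), zero-pads to 4× the next
power of two, and takes the rFFT with physical scaling; `k*` is the
positive-frequency argmax of the real part refined by parabolic
interpolation through the peak bin (error < 0.2 % against the closed-form
transform of the kernel factors, which the test suite uses as an
independent oracle). Ties resolve to the lowest frequency.

Periodic (multi-wave) input is represented by convolving the burst with a
finite Dirac comb of `n_waves` teeth at the inter-wave interval; below the
critical interval `IWI_crit = 1/(v k*)` the comb harmonics dominate the
spectrum and push the pattern to higher frequencies.

The theoretical robustness `Ψ_κ = Re[κ̃(k*)]² / Σᵢ Re[κ̃(kᵢ)]²` (DC bin
excluded, matching the weight-spectrum measure `Ψ_w`; the raw value is
grid-dependent, so reported values are referenced to a stated reference
condition). The spec of the measured counterpart `Ψ_w` uses the full
discrete spectrum from `−k_N` to `k_N`, so a noiseless sinusoid scores
exactly 0.5 (its power splits across the `±k` pair).

## Mean-field integration

Forward Euler with hard clipping to `[0, 1]` after each step, the kernel
mirrored on odd steps (alternating wave direction), an optional hard arbor
mask multiplying the update, and zero-padded convolution — the layer is
embedded in a silent surround, since waves enter and exit a finite layer.
The default step satisfies `η·dT·max|κ̃| = 0.1` (stability with margin).
For *quantitative* frequency measurements the sweeps use a smaller factor
of 0.02: at 0.1 the boundary-truncation error of the convolution leaves a
visible second-order imprint at the layer ends, while halving 0.02 again
changes nothing. Initial weights are 0.5 plus Gaussian noise of SD 0.05 —
small relative to the weight range but large enough to seed every unstable
mode above the boundary-truncation floor; with much weaker noise the
pattern nucleates from the layer ends and freezes in domain-wall defects
that broaden the measured spectrum.

## Spiking simulation

The 1 ms loop is compiled with numba. EPSP summation uses two exponential
accumulator states, so the per-step cost is proportional to the number of
spikes, not synapses. Within a time step, input spikes are generated and
injected first, then the output spike decision is taken, then plasticity
is applied — an input spike pairs with strictly earlier output spikes and
an output spike pairs with all input spikes up to and including its own
bin, so coincident pairs are counted exactly once (the asymmetric rule
assigns them zero). The output gain `R_out` (or LIF threshold `ϑ`) is
calibrated on a 10 s plasticity-free dry run so wave-driven output rates
land mid-range between 10 and 100 Hz. The learning rate is "small" in the
source model without a stated value; the desk-scale default `η = 5×10⁻³`
per pairing brings a 500-input layer to a saturated steady state within
~400 waves while keeping single-pairing steps ≪ the weight range.

## Idealized wave input

Plane waves enter at one edge and traverse the layer; isolated-wave
schedules insert a ≥ 5 s blank gap after each passage so output activity
decays to zero, and alternate direction every wave (every 100 waves in
multi-wave runs). Optional lognormal wave speeds (floored at 0.05 mm/s)
and shifted-lognormal inter-wave intervals (never shorter than the burst)
are parameterized by their linear-scale mean and SD. Local correlations
are generated in two stages: stage-1 Bernoulli spikes at rate
`R/(1+2c)`, then a stage-2 spike with probability `c` in each immediate
lattice neighbour of a stage-1 spiker (2 neighbours in 1D, 4 in 2D — the
minimal reading of "neighbouring"), keeping realized rates constant while
adding instantaneous neighbour correlations. Background firing applies
only to neurons not currently bursting, and continues through blank gaps.

## Complex retinal waves

Starburst amacrine cells (SACs) and retinal ganglion cells (RGCs) sit on
64×64 lattices (34 µm spacing); every cell receives input from the SACs
within 120 µm (36 on the full lattice, fewer at edges; no wrap-around).
An excitation variable decays with time constant 0.1 s and is driven by
the number of currently active SACs; a SAC crossing threshold 6 transmits
for 1 s, then draws a refractory period from N(40 s, 20 s) truncated at
zero, after which its excitation resets; spontaneous activations occur
with probability 0.0035 per SAC per 0.1 s step. RGC upward crossings of
threshold 10 are the wave events.

The model step equals the decay constant, where a forward-Euler reading of
the rate equation pins the excitation at (a scaled copy of) the
instantaneous neighbour count — at most 3.8 after scaling, below both
thresholds, so no wave could ever propagate. The package therefore
integrates the accumulation form `X ← X e^{−Δt/τ} + n`, which preserves
the stated decay constant, makes the thresholds reachable, and yields the
documented regime of wavefronts winding between refractory domains
(relaxation and Euler variants remain available behind a flag; neither
nucleates waves). The first step ignites a synchronized lattice-wide
transient (every cell starts eligible); analyses discard a 200 s settling
period.

Wave speed is controlled by rescaling event times by `F_t ≤ 1` rather than
retuning the lattice model (which would change the wave morphology);
rescaled events trigger 0.1 s, 50 Hz Bernoulli bursts, with overlapping
windows of one RGC merged.

## Wave tracking

Spike rasters are binned into a 100 ms rate movie (Hz). The movie is
smoothed with a Gaussian (σ = 34 µm in space, 100 ms in time), values
below 10 are zeroed, and 8-connected active domains are found per frame.
Each domain's centre of mass is computed from the *unsmoothed* rates
inside the domain. Domains in one frame with COMs closer than 680 µm share
a wave ID, and a domain inherits the ID of any previous-frame COM within
680 µm (unions take the size-weighted COM). Each track is zero-padded,
Gaussian-smoothed in time (SD 0.1 s), trimmed by two points at each end,
and retained only if it lasts > 0.5 s, covers ≥ 1000 space-time bins, and
keeps its time-averaged COM inside the central 44×44 cells. Speed is path
length divided by the trajectory's spanned time ((n−1) × 0.1 s for n
retained points — the elapsed time between the first and last COM; the
printed source value lies between this and the n-bin reading, and the
ambiguity is ~10 %).

## Desk-scale study sizes

The bundled verification protocols are scaled down from the full study:
spiking sweeps use 6 trials of 400 waves per parameter set (rather than 16
trials of longer runs), mean-field sweeps 16 noise seeds, and the
complex-wave analysis one 2000 s rescaled segment (≈ 9700 s of lattice
time). `scripts/acceptance.py --seed N --out results.json` recomputes the
headline numbers from scratch at these sizes.

## Known limitations

* The synthetic wavefronts are kinematically ideal (no topographic jitter
  or conduction delays); agreement of simulation with theory here does not
  certify behaviour on biological recordings.
* The retina model's published description does not fix its discretization;
  absolute wave speeds carry a ~5–10 % integrator ambiguity (the rescaling
  ratios between slow/medium/fast conditions are robust).
* Raw robustness values (`Ψ_w`, `Ψ_κ`) depend on the spectral grid; only
  values referenced to a stated reference condition are comparable.
* Mean-field integration is first-order; quantitative spectral
  measurements should use the step-converged safety factor (0.02), not the
  stability default.
* 2D mean-field handling covers axis-aligned plane waves only; oblique and
  complex 2D waves are the spiking simulator's domain.
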