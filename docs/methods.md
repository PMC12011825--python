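# Methods

## Spike generation

A Purkinje cell is an inhomogeneous Bernoulli process on a regular grid
with timestep dt = 0.05 ms. The instantaneous rate N(t) (Hz) maps to a
per-step spike probability p(t) = N(t)·dt/1000, clamped at 1 (the clamp is
unreachable below 20 kHz at the default dt). All cells of an ensemble
share p(t) — the synchronized microzone code — but draw independent
outcomes. An absolute refractory period (default 1 ms = 20 steps) forbids
a spike closer than 1 ms after the cell's previous spike; two spikes
exactly 1 ms apart are allowed. The refractory period makes the realized
rate lower than nominal: the train is a renewal process with mean ISI
refractory + dt/p − dt, i.e. ≈5.95 ms (realized ≈168 Hz) at a nominal
200 Hz. No correction is applied — the generator is simulated as
described, and analyses compare like with like.

Randomness: one root `numpy.random.SeedSequence` per simulation, spawned
into per-cell substreams. Identical seeds give bit-identical rasters, and
the first k cells of an ensemble are unchanged when more cells are added.

Rate profiles are constant or sinusoidal, N(t) = b + a·sin(2πt/λ + φ₀),
with validation that b − a ≥ 0 (rates never negative) and φ₀ = 0 by
default (start at baseline, rising). Published descriptions of the step
cycle give both a 50–200 Hz and a 50–250 Hz range; the convergence-sweep
experiment uses 50–250 Hz (a = 100, b = 150) and the linearity sweep
50–200 Hz, following the respective figure conventions. The 400 ms
group-synchrony cycle is unspecified; it uses the same 50–250 Hz band
with λ equal to the cycle duration. An alternative sinusoid
parameterisation y = a·sin(zx/π) + b is supported through the mapping
λ = 2π²/z with x in milliseconds (an involution, converters in
`rate_profiles`).

## Convergence statistics

DCN decoding is proxied by counting spikes from all afferents in 1 ms
bins and taking a trailing rolling mean of consecutive counts
(window = 2 bins by default — the minimal reading of "consecutive" —
"valid" edges, no padding invented). Metrics:

- CV of the binned counts over a cycle (population SD / mean).
- Jitter: mean |Δcount| between consecutive bins, divided by the
  convergence ratio, ×100. Absolute differences are used because the
  signed mean is ≈0 by construction.
- Reliability: Pearson correlation over all pairs of n independently
  simulated cycles, computed on the integrated series by default (raw
  counts optional).

## Charge entry

The quantum kernel rises linearly over rise_ms (default one timestep —
"fast rise" with minimal invention; the exact published waveform shape is
not specified beyond rise/peak/decay) to a peak of exactly 1, then decays
as exp(−t/τ). The tail is truncated below 1e-6 of peak, giving a finite
support (≈13.8·τ) for exact discrete convolution; the truncation bias on
the kernel integral is <1e-5 relative. Superposition is the linear
convolution of the summed spike train with the kernel — no saturation, no
voltage dependence — and conserves charge exactly when the decaying tail
beyond the raster is retained (`keep_tail=True`); by default traces are
cut to the raster duration, as displayed data would be.

The linearity sweep simulates a fresh 40-cell ensemble per rate
(50–200 Hz inclusive; the default 1 Hz step gives 151 runs — the stated
endpoints govern over a literal count of 200) and tabulates the 200 ms
mean and CV per decay constant. Rolling means of the current (0.1, 0.5,
1 ms) use the same trailing-window convention as the count integration.

## Wiring and synchrony

Group wiring draws, for each DCN independently, a uniformly random
size-40 subset of the 400 afferents (without replacement within a DCN —
a cell is or is not an afferent — with "replacement" across DCNs, i.e. no
cross-constraints). The somatic-subregion mode wires 40 sites to random
30-of-60 samples; the pool of 60 exceeds the ~40 cells with significant
contact because total afferent counts are higher. Synchrony metrics are
computed on the 1 ms-rolled traces as displayed: pointwise across-DCN SD
and CV, and mean pairwise correlation. When comparing convergence ratios
the pointwise SD is normalized by the mean current, since the raw sum
scales with the number of afferents while the sampling error of the
per-afferent mean scales as 1/√n.

## Collateral analytics

The contact-count distribution is Binomial(m, z/n) per DCN; the joint
probability that exactly x of n DCNs receive ≥ y contacts is taken as
Binomial(n, q) with q = P(≥y) — DCNs treated as independent even though
the wiring fixes the total contact count at m·z. This is implemented as
printed; `simulate_wiring_counts` is the exact Monte-Carlo wiring model
(each presynaptic cell contacts a random z-subset) and the tests use it
to bound the discrepancy rather than "correcting" the analytic form (for
the default n=50, z=5, m=10 the marginal expectation n·P(≥1) is exact and
the simulation agrees within Monte-Carlo error).

Collateral resampling draws, for each of 50 DCNs, 5 values (the assumed
1:5 nucleo-nuclear divergence; it is not known) with replacement from the
group's per-millisecond count distribution and averages them. For a
near-normal source the CV of the means is smaller by √5. The per-bin
count simulation at 147.5 Hz (a cycle timestep taken as a direct input —
it is not derivable from the stated cycle parameters) keeps the 1 ms
refractory by default; the binomial-oracle test disables the refractory,
where E[count] = convergence·rate·bin/1000 holds exactly.

## Phase shift

For f(t) = a·sin(2πt/λ) + b the combined curve f + w·f′ uses the exact
analytic derivative; w (ms) is the free weight of the plasticity term
(defaults {1, 2.5, 5, 10} span small-to-large relative influence; no
numeric values are published for it). Closed form: leftward shift
φ = atan(2πw/λ), so shift_ms = φλ/2π → w as λ → ∞ (the flat line in ms),
and shift in degrees grows as λ shrinks. The numeric estimator removes
the series means, takes the circular FFT cross-correlation, and refines
the integer-lag peak by parabolic interpolation; positive = earlier in
time. It requires a shared grid covering an integer number of wavelengths
with the endpoint excluded; on a 10⁴-point grid it matches the closed
form to ≪0.1°. Both routes are reported by `wavelength_sweep`.

## Problem sizes and what the tests show

Default experiment sizes follow the modelled anatomy (400→50 wiring at
40:1, 40 subregions of 30-of-60, 200–400 ms cycles at dt = 0.05 ms). The
statistical test battery uses reduced replication (10–20 seeds or cycles,
5 Hz linearity steps, 2×10⁴–10⁵ Monte-Carlo repetitions) — enough that
the asserted orderings and tolerances are stable across seeds.

The generator idealises Purkinje firing: no spike-timing structure beyond
the shared probability and refractoriness, no complex spikes, no
heterogeneity of quanta or decay constants across synapses, and no
short-term plasticity in the current simulations (the phase-shift model
is analytic and separate). Passing tests therefore demonstrate the
statistical consequences of the stated assumptions — convergence noise
reduction, linear charge coding, sampling synchrony, resampling
tightening, derivative phase advance — not properties of recorded data.

## Known limitations

- Bouton multiplicity is normalized into the unit quantum (one quantum
  per spike per afferent); a bouton-count multiplier would only rescale.
- The joint collateral formula's independence approximation is kept, as
  published; use the Monte-Carlo wiring model where exactness matters.
- Multi-peaked rate cycles and DCN output spiking (intrinsic ~90 Hz
  pacemaking, excitatory dendritic input) are out of scope.
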