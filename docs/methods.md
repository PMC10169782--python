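# Methods

## Encapsulation statistics

Loading is modeled as a homogeneous Poisson process: the number of cells in a
droplet core is Poisson with mean λ = cell concentration × core volume
(1 pL = 10⁻⁹ mL). The module exposes the forward map (λ → occupancy pmf with
an explicit tail mass above `k_max`, default 10, so truncation is never
silent) and the inverse map from an observed empty fraction, λ = −ln p₀.
Probabilities are evaluated through the Poisson log-pmf, which remains
accurate far beyond the dilute regime (λ ≫ 20) where direct products
underflow. No default is shipped for an OD600 → cells/mL factor: it is
strain- and spectrophotometer-specific and must be supplied by the user
(platform work of this kind typically loads at OD600 ≈ 0.05).

A note on internal consistency of the dilute regime: an 80% empty fraction
implies λ ≈ 0.223 and a single-cell purity among occupied droplets of
λe^{−λ}/(1−e^{−λ}) ≈ 0.893. Purity figures near 98% sometimes quoted for
such regimes are not achievable under a single Poisson λ with 20% occupancy;
the package implements the formula and reports what it implies.

## Competition model

Growth in any well-mixed compartment follows the canonical Monod
consumer-resource system

    dN_i/dt = μ_i(S) N_i,   μ_i(S) = μ_max,i S / (K_s,i + S)
    dS/dt   = feed − Σ_i μ_i(S) N_i / Y_i

with substrate in mM, populations in arbitrary abundance units
(OD-equivalents in the default parameter sets, yield Y in OD-equivalent per
mM), and no death or maintenance term — populations freeze once substrate is
exhausted. `feed` defaults to 0 (plain batch); a constant-feed term is
exposed so fed-batch operation is available, since serial-transfer protocols
are sometimes described either way. Integration uses LSODA with relative
tolerance 10⁻⁸ and a scaled absolute tolerance; substrate is clamped at zero
inside the right-hand side. The mass-balance identity
Σ ΔN_i/Y_i = ΔS + ∫feed holds to ~10⁻¹³ relative in practice and is asserted
to within 10× the integrator tolerance over randomized parameter sweeps.

Serial batch transfers carry `dilution_factor` (default 0.01) of every
population into fresh medium at `substrate_S0` (default 50 mM) every
`duration_h` (default 48 h). The default inoculum of the first transfer is
the biomass a stationary culture would contribute after that dilution.

The droplet regime grows each occupied droplet as an independent batch on a
private substrate core. Founder compositions are drawn per droplet —
`exact-single` (one founder, multinomial across strains) or `poisson`
(k ~ Poisson(λ) founders drawn i.i.d.; k ≥ 2 droplets host a within-droplet
competition on the shared private core). Droplets with identical founder
composition are deterministic replicates, so each unique composition is
integrated once and weighted by its count; this makes 10⁵-droplet ensembles
cost a handful of ODE solves. A `sampling="expected"` mode replaces the
multinomial draw with exact expected weights, giving the deterministic
infinite-ensemble limit; `multinomial` mode is driven by one
`numpy.random.Generator` seeded from `rng_seed`, so fixed seeds give
bit-identical trajectories. Pooled frequencies after transfer *t* become
founder frequencies of transfer *t+1*, mirroring bulk droplet disruption and
re-encapsulation.

In the single-founder, full-consumption, negligible-founder-biomass limit
the pooled update has the closed form f′ = r f/(r f + 1 − f) with
r = Y_yield/Y_rate; the simulator is tested against it to 10⁻⁶ (deterministic
mode) and to 3 binomial standard errors (10⁵-droplet stochastic mode).

Default kinetic scenario (`rate-vs-yield`): μ_max 0.9 vs 0.7 h⁻¹, equal
K_s = 0.5 mM, yields 0.02 vs 0.03 OD-eq/mM. The 1.5 yield ratio is the ATP
stoichiometry ratio of mixed-acid (3 ATP/glucose) versus homolactic
(2 ATP/glucose) fermentation; the μ_max values are representative of
lactococcal monoculture growth, where the efficient fermentation mode costs
roughly 20–25% of the maximum growth rate. The default founder biomass
(0.015 OD-equivalent) corresponds to one cell in a ~65 pL core; with 50 mM
glucose this allows ~60-fold growth per droplet, consistent with tens of
cells per droplet after overnight growth. Extinction is flagged below 10⁻¹²
of the total population — a numerical floor, reported rather than silently
applied.

The observed endpoint of real rate-vs-yield droplet competitions (e.g.
~99% yield specialist within a few transfers) depends on kinetic parameters
not derivable from frequency data alone; the package asserts the direction
and the analytic update, not any particular experimental endpoint.

## Image quantification

Pipeline: unsharp-mask sharpening (clamped to the bit depth) → Canny edges
(σ = 2 on the min–max-normalized image) → circular Hough voting over
`radius_range` (1 px steps) → peak selection with non-maximum suppression at
`min_center_separation` (default: the minimum radius, since droplets cannot
overlap) → two validation passes → shrunken circular mask → thresholded sum.

The validation passes exist because Hough votes alone are promiscuous:

1. *Circumference support*: a candidate circle must have ≥ 48% of its
   rasterized circumference on edge pixels and edge hits in ≥ 85% of twelve
   30° sectors. Short tangent arcs (a small circle hugging a piece of a large
   rim) fail both.
2. *Outer-rim refinement*: a rim of finite width yields two concentric edge
   circles and the strongest vote can lock onto either; the droplet radius is
   the outer one, so the radius is snapped to the outermost local maximum of
   the vote profile within 20% above the voted radius.

Circles intersecting the image border are excluded rather than partially
measured (partial interiors bias sums). Coordinates are 0-based (x, y) =
(column, row) pixels; physical sizes use `pixel_size` only for reporting.

Measurement sums fluorescence pixels *strictly above* a threshold inside a
mask of radius `mask_shrink × r` (default 0.85, excluding the bright rim).
The threshold is an absolute intensity or `"auto"` (Otsu on the per-image
fluorescence histogram), resolved once per image and recorded in the output
table and metadata. Thresholding is what makes the readout independent of
droplet size: sub-threshold interiors contribute nothing regardless of
radius. Detection runs on the brightfield channel and measurement on the
fluorescence channel; workflows that overlay the channels before analysis
can pass the overlay as the detection channel instead.

Calibration (`calibrate_cells`) is an ordinary least-squares line from
fluorescence sum to cell count with R², slope standard error, and a
prediction helper.

## Synthetic data

The micrograph generator renders monodisperse circular droplets (radius
drawn uniformly, default 31–45 px at 0.5 µm/px, i.e. 30–45 µm diameters)
with bright rims (default 3 px wide) on a brightfield background, placed by
rejection sampling with a 4 px clearance and full-frame containment; an
infeasible packing raises an error after a bounded number of attempts. Cells
are isotropic Gaussian spots (σ = 1.5 px, amplitude ≈ 30% of the dynamic
range) placed within 0.6·r of the center, on the fluorescence channel only.
The per-droplet `true_signal` is the pixel sum of the rendered, noise-free
spot layer, so truth and an ideal integration of the clean image differ only
by quadrature.

Noise is additive Gaussian. The benchmark's SNR knob sets the *brightfield*
noise as rim contrast / SNR — the quantity that controls how hard detection
is. Fluorescence read noise is a separate small fixed scale (default σ = 150
counts on a 16-bit range) because cell spots are orders of magnitude brighter
than camera noise on the measurement channel; the benchmark threshold
(850 = background + 5σ of read noise, ~4% of spot amplitude) is therefore
both far above noise and far below signal. The standard fixture set is 3
images × 20 droplets at SNR ∈ {3, 5, 10} with fixed seeds.

What the generator does *not* emulate: shell refraction and depth-of-field
optics, uneven illumination, droplet polydispersity beyond uniform jitter,
overlapping or border-clipped droplets, motile-cell blur, and spot saturation
at high cell densities (stacked spots can clip at the bit depth; the dense-
droplet calibration tests use a lower amplitude for that reason). Passing
the benchmark therefore demonstrates correctness of the algorithms, not
robustness to every real-microscope artifact.

## Problem sizes and numerical choices

Defaults are chosen so the whole suite runs in well under a minute of ODE
work: serial competitions use 8–15 transfers, droplet ensembles 10³
(deterministic) to 10⁵ (stochastic) droplets, Monte-Carlo occupancy checks
10⁶ draws, and the imaging benchmark three 768×768 images. Statistical
assertions use 3-standard-error bounds at these sizes. Seeds are fixed
everywhere; hypothesis runs derandomized.

## Reporting

Composition tables are long-format (sample, taxon, relative abundance in %);
duplicate rows are summed on construction and per-sample totals validated to
≤ 100% + rounding slack. Fold enrichment is after/before at full precision
with a rounded integer convenience column; a zero baseline is an error that
points the user to absolute changes instead. Upstream amplicon processing
(denoising, taxonomy) is explicitly out of scope.
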