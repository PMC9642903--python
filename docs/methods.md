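# Methods

## Model overview and assumptions

The package treats color perception as a three-stage linear-filtering and
reconstruction process on a retinotopic grid:

1. **Opponent coding.** Stored RGB values are taken as the model's working
   space and mapped per pixel to red–green, blue–yellow and achromatic
   intensity channels by a fixed invertible 3×3 matrix whose luminance row
   uses the Rec. 601 weights (0.2989, 0.587, 0.114). No gamma decoding is
   applied inside the model pipeline; whether the stimulus is
   gamma-encoded is immaterial to the model's algebra, and the choice is
   isolated from evaluation (below).
2. **Receptive fields.** Single-opponent responses are normalized Gaussian
   low-passes; double-opponent responses are discrete-Laplacian high-passes.
   Both assume isotropic, space-invariant receptive fields — no
   orientation-selective double-opponent variants.
3. **Filling-in.** The perceived surface of each channel solves the
   steady-state Poisson equation ΔO = −DO: the model assumes filling-in is
   fast relative to stimulus dynamics (the diffusion equation's transient is
   dropped) and isomorphic — literal activity spreading on a neural sheet,
   here a recurrent grid of spiking ensembles with nearest-neighbor
   (horizontal) connections.

The perceived image is a per-pathway convex mixture of the low-pass planes
and filled-in surfaces, weighted by α_c (chromatic) and α_i (intensity) with
β = 1 − α, then inverted back to RGB. The mixing weights are free
parameters representing single- vs. double-opponent dominance; the model
deliberately does not prescribe a single value — differences in α are its
account of individual differences in color perception.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| W, σ | 21, 5 (preset "small": 11, 3) | px | SO Gaussian window and width |
| τ | 0.25 | – | diffusion step weight; ≤ 0.25 guarantees explicit-iteration stability on the 5-point stencil |
| α_c, α_i | 0.5, 0.5 | – | filled-in surface weight per pathway |
| n_neurons | 20 | – | spiking neurons per pixel ensemble |
| radius | 1.2 × channel max | channel units | represented range of each ensemble (RG ≤ 0.5, BY ≤ 1/3, I ≤ 0.9999 for [0,1] stimuli) |
| intercepts | uniform (−1, 0.95)·radius | – | rectified-linear tuning-curve zero crossings |
| max rates | uniform (100, 200) | events/s | firing rate at the preferred end of the range |
| τ_syn, dt | 5 ms, 1 ms | s | first-order synapse and simulation step |
| run_time | 1.0 | s | SNN simulated duration; surface = decode averaged over the final 20% |
| snapshot n_steps | 200 | – | partial-filling step count (calibration, see below) |

The snapshot default of 200 steps is a documented calibration, not a model
constant: it is chosen so that on a 100×100 canvas a 10 px square fills
(fill ratio > 0.8) while an 80 px square does not (< 0.2), matching the
qualitative size dependence of mesoscale V1 recordings.

## Numerical choices

**Boundary rules.** The paper-style update is boundary-agnostic; we default
to a Dirichlet-0 frame (one clamped border pixel), which pins the Poisson
solution uniquely and makes oracle tests exact. A replicate/Neumann rule is
available; its operator is singular, so sources are projected to zero mean,
the solution is normalized to zero mean, and results carry a `projected`
flag. Receptive-field convolutions use replicate-edge padding so constant
images are exact fixed points and the frame injects no spurious contrast.

**Sign bookkeeping.** The double-opponent kernel has +4 at its center, the
negative of the conventional ∇² stencil. Feeding source = L∗X into
I += τ(source + Δ_std I) therefore has fixed point I = X (up to boundary
terms); tests assert this identity directly.

**Convergence criterion.** "Converged" means the spectral error bound —
max-abs Poisson defect divided by the smallest eigenvalue of the negated
operator (known in closed form for both boundary rules) — is below `tol`,
so `tol` bounds the distance to the exact solution. A plain small-update
rule would stop while the slowest smooth mode still carries an error of
order tol/λ_min, which grows with grid size; the spectral form removes that
dependence. The per-step update (τ × defect) is then far below tol as well.

**Decoder regularization.** Decoders solve a ridge least-squares problem
with σ = reg × max rate and reg = 0.01. Spike generation is a deterministic
integrate-to-threshold realization of the rectified-linear rate with
seeded, desynchronized initial phases, so decoded rates carry no stochastic
noise; the conventional heavier ridge (reg ≈ 0.1) would only add static
decoding bias, which the recurrent Poisson loop amplifies by roughly
1/(τ·λ_min). With reg = 0.01 the 16×16, 20-neuron network tracks the
converged iterative solution to ~2% of dynamic range.

**NEF dynamics mapping.** Target dynamics dI/dt = κ(source + ΔI) with
κ = τ/τ_syn are realized by decoding τ_syn·f(x) + x = τ(source + ΔI) + I on
the recurrent connection — i.e. the recurrent transform *is* the diffusion
feedback — and τ·source on the input. The fixed point is the Poisson
solution for any synaptic time constant; κ only sets the filling speed.
Because ensembles approximate each pixel, the spiking surface never reaches
an exact steady state; results report the honest residual and are averaged
over the final 20% of the run.

**Degenerate inputs.** Zero-luminance pixels have undefined chromaticity and
are flagged, not NaN-propagated; zero-variance profiles make R² undefined
and are flagged; empty masks and non-finite sources are errors.

## Evaluation choices

u'v' chromaticity assumes sRGB primaries, D65 white and standard gamma
decoding (the display model is otherwise unspecified); the choice is
confined to the evaluation module, and a `decode_gamma=False` path exposes
the linear-RGB invariances. Chroma is summarized as mean u'v' distance from
the D65 achromatic point over a region.

The perceptual-distance contract is a weighted squared L2 over pluggable
feature layers, averaged over pixels. The shipped extractor is the identity
(pixel-space MSE): it is weight-free, deterministic and self-contained;
learned feature stacks can be plugged in without changing callers.

The Retinex baseline is the single-scale, non-logarithmic form, per RGB
channel, with the surround kernel exp(−(x²+y²)/s²) normalized over the full
image support (realized at odd dimensions for exact center alignment) and
replicate-edge padding. Its signed output is kept for analysis; the display
variant adds mid-gray 0.5 and clips. The documented scale grid for chroma
sweeps is s ∈ {1, 2, 5, 10}.

## Synthetic stimuli: what they do and do not show

All quantitative results use stimuli the package generates: uniform centered
squares (5–80 px), color-assimilation grids (45° lines, width 3 px, steps
15/50, chroma amplified ×4 in opponent space over a grayscale base — the
amplification is defined in opponent space because "saturation ratio" has no
single operational definition), multiplicatively tinted patch scenes
standing in for photographs under colored illuminants, and a random
rectangular-patch color scene standing in for natural images. These capture
the geometry and statistics the model's mechanisms act on (edges, uniform
surfaces, global tints) but not natural-image content: passing tests show
the mechanisms behave as designed, not that reconstruction quality on
photographs matches any particular reference. Profile comparison emulates
the analysis of cortical population recordings (cut, band-average, 1-D
Gaussian smoothing with σ = 2, edge-anchored alignment, OLS R²); the
band half-width is configurable (default 2 px).

## Problem sizes

Tests and the acceptance script use 32×32 solver grids (oracle battery),
16×16 spiking networks at 20–80 neurons per pixel with 1 s simulated time,
100×100 snapshot runs, and 90×120 perception pipelines — sizes at which
every backend, including the exact sparse oracle, runs comfortably on one
CPU while exercising the same code paths as larger images.

## Known limitations

- The SNN backend is validated against the iterative solver, not against a
  Nengo reference; its accuracy depends on ensemble size and radius, and a
  pure integrator configuration (zero recurrent function) drifts with
  decoding bias, as any neutrally stable spiking integrator does.
- Per-pixel scalar ensembles only; no multi-dimensional ensembles, LIF or
  adaptive neuron models, or learning rules.
- The α weights are global; regionally varying dominance (plausibly how the
  brain sets them) is not modeled.
- No ICC/display handling beyond the sRGB assumption in evaluation; gamut
  handling is plain clipping at export.
- The Retinex operator builds an explicit full-support kernel and is capped
  at 512×512 images.
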