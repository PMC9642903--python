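# chromafill

A computational model of human color perception built from biologically
motivated parts: opponent color channels, single- and double-opponent
receptive fields, and perceptual *filling-in* — the reconstruction of
complete colored surfaces from edge signals — realized as a Poisson-equation
solver and, equivalently, as a recurrent spiking neural network (SNN) built
on Neural Engineering Framework (NEF) principles.

It is aimed at computational-neuroscience and vision researchers who want a
compact, fully deterministic sandbox for phenomena such as size-limited
filling-in in primary visual cortex, the color assimilation grid illusion,
and color constancy under tinted illuminants, with a single-scale Retinex
operator as a classical baseline.

## The model

An RGB stimulus (values in [0, 1]) is mapped per pixel to opponent channels

```
(RG, BY, I)ᵀ = M_opp (R, G, B)ᵀ,   M_opp = [ 1/2  −1/2    0  ]
                                           [ 1/6   1/6  −2/6 ]
                                           [  a     b     c  ]
```

with the Rec. 601 luminance weights a = 0.2989, b = 0.587, c = 0.114.
Single-opponent (SO) responses are Gaussian low-passes of each plane
(window W = 21 px, σ = 5 by default); double-opponent (DO) responses are
convolutions with the discrete Laplacian L = [0 −1 0; −1 4 −1; 0 −1 0].

Perceived surfaces O solve the steady-state Poisson equation ΔO = −DO,
computed three ways: an exact sparse solve (oracle), the explicit diffusion
iteration

```
I_k = I_{k−1} + τ · (DO + Δ_std I_{k−1}),   τ = 0.25,
```

and a recurrent SNN in which each pixel is a 20-neuron ensemble of spiking
rectified-linear units, wired with the same five-point stencil through the
NEF dynamics mapping. Stopping the iteration early ("snapshot" mode)
reproduces the partially filled surfaces seen in mesoscale cortical
recordings of large stimuli.

The perceived image mixes low-pass and filled-in surfaces per pathway,

```
P_RG = β_c·SO_RG + α_c·O_RG,   P_BY = β_c·SO_BY + α_c·O_BY,
P_I  = β_i·I_LPF + α_i·O_I,    β = 1 − α,
```

and is mapped back to RGB with M_opp⁻¹ (clipped to gamut only at export).
α → 0 gives soft, saturated, low-pass perception; α → 1 gives edge-driven,
illuminant-discounting perception.

## Worked example

Snapshot filling-in of centered red squares (5–80 px on a 100×100 canvas,
200 diffusion steps), quantified by the *fill ratio* — mean activity in the
square's core relative to its inner edge band:

```
$ chromafill squares --out scratch/squares
side   5 px  fill ratio 0.998
side  10 px  fill ratio 0.984
side  20 px  fill ratio 0.796
side  40 px  fill ratio 0.238
side  80 px  fill ratio 0.008
```

Small squares fill completely (ratio ≈ 1) while large squares stay hollow
(ratio ≈ 0) at the same step count — the size-limited filling-in signature
observed in V1 population imaging.

From Python, sweeping the chromatic surface weight on the same stimulus:

```python
from chromafill.stimuli import SquareStimulusSpec, make_square
from chromafill.pipeline import PerceptionConfig, PerceptionWeights, perceive
from chromafill.evaluation import perceptual_distance

img = make_square(SquareStimulusSpec(canvas=(64, 64), side=20))
for ac in (0.0, 0.5, 1.0):
    cfg = PerceptionConfig(weights=PerceptionWeights(alpha_c=ac, alpha_i=0.5))
    print(ac, round(perceptual_distance(img, perceive(img, cfg)), 4))
```

prints pixel-space distances `0.0 0.1985`, `0.5 0.1857`, `1.0 0.1789`:
with the fully converged solver every weighting reconstructs the square
closely, and the differences trace how much low-pass blur (α_c = 0) versus
edge-sharpened reconstruction (α_c = 1) enters the percept.

Other subcommands: `chromafill perceive` (image → perceived image +
intermediates), `sweep` (grid over α_c, α_i), `grid-illusion` (assimilation
stimulus generator), `retinex` (baseline renderings). Every run writes its
resolved configuration and seed alongside the outputs.

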