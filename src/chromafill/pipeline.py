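"""End-to-end perception: stimulus -> opponent channels -> receptive-field
filtering -> filling-in -> weighted recombination -> perceived RGB image.

The perceived opponent planes are weighted mixtures of the single-opponent
low-pass planes and the filled-in surfaces reconstructed from the
double-opponent planes:

    P_RG = beta_c * SO_RG + alpha_c * O_RG
    P_BY = beta_c * SO_BY + alpha_c * O_BY
    P_I  = beta_i * I_LPF + alpha_i * O_I,      beta = 1 - alpha.

alpha = 0 yields pure low-pass (single-opponent) perception; alpha = 1
yields pure filled-in (double-opponent-derived) surfaces.  With filling-in
disabled (ablation) the O planes are the raw Laplacian channels, so
alpha = 1 reduces the whole model to a high-pass filter of the image.
Out-of-gamut values arising from the recombination are preserved through
the algebra and clipped only at final image export.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from chromafill.colorspace import OpponentImage, opponent_to_rgb, rgb_to_opponent
from chromafill.receptive_fields import ChannelSet, GaussianKernelSpec, compute_channels
from chromafill.filling_in import (
    FillinProblem,
    FillinResult,
    fillin_direct,
    fillin_iterative,
    fillin_snn,
)
from chromafill.nef_core import EnsembleSpec, SynapseSpec

# Opponent-plane extrema for stimuli in [0, 1]; sets per-channel SNN radii.
_CHANNEL_MAX = {"rg": 0.5, "by": 1.0 / 3.0, "i": 0.9999}


@dataclass(frozen=True)
class PerceptionWeights:
    """Mixing weights: alpha scales the filled-in surface, beta = 1 - alpha
    the single-opponent low-pass plane, separately for the chromatic (c)
    and intensity (i) pathways."""

    alpha_c: float = 0.5
    alpha_i: float = 0.5

    def __post_init__(self) -> None:
        for a in (self.alpha_c, self.alpha_i):
            if not 0.0 <= a <= 1.0:
                raise ValueError("alpha weights must lie in [0, 1]")

    @property
    def beta_c(self) -> float:
        return 1.0 - self.alpha_c

    @property
    def beta_i(self) -> float:
        return 1.0 - self.alpha_i


@dataclass
class PerceptionConfig:
    """Everything that determines one perception run."""

    kernel: GaussianKernelSpec = field(default_factory=GaussianKernelSpec)
    weights: PerceptionWeights = field(default_factory=PerceptionWeights)
    backend: str = "iterative"  # direct | iterative | snn
    mode: str = "converge"  # converge | snapshot (iterative backend)
    tol: float = 1e-5
    n_steps: int = 200
    boundary: str = "dirichlet"
    tau: float = 0.25
    fillin_enabled: bool = True
    n_neurons: int = 20
    run_time: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in ("direct", "iterative", "snn"):
            raise ValueError("backend must be direct, iterative or snn")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kernel"] = {"W": self.kernel.W, "sigma": self.kernel.sigma}
        d["weights"] = {"alpha_c": self.weights.alpha_c, "alpha_i": self.weights.alpha_i}
        return d


@dataclass
class PerceptionResult:
    """Perceived planes plus every intermediate, for inspection."""

    p_rg: np.ndarray
    p_by: np.ndarray
    p_i: np.ndarray
    opponent: OpponentImage
    channels: ChannelSet
    fill_results: dict  # channel name -> FillinResult | None


def _fill_plane(
    do_plane: np.ndarray, cfg: PerceptionConfig, channel: str, seed_offset: int
) -> FillinResult:
    problem = FillinProblem(source=do_plane, boundary=cfg.boundary, tau=cfg.tau)
    if cfg.backend == "direct":
        return fillin_direct(problem)
    if cfg.backend == "iterative":
        return fillin_iterative(problem, mode=cfg.mode, tol=cfg.tol, n_steps=cfg.n_steps)
    spec = EnsembleSpec(
        n_neurons=cfg.n_neurons,
        radius=1.2 * _CHANNEL_MAX[channel],
        seed=cfg.seed + seed_offset,
    )
    return fillin_snn(problem, ensemble_spec=spec, run_time=cfg.run_time)


def perceive_channels(img: np.ndarray, cfg: Optional[PerceptionConfig] = None) -> PerceptionResult:
    """Run the model up to (but not including) the inverse opponent transform."""
    if cfg is None:
        cfg = PerceptionConfig()
    opp = rgb_to_opponent(img)
    channels = compute_channels(opp, cfg.kernel)

    w = cfg.weights
    if cfg.fillin_enabled:
        # Surfaces weighted by alpha = 0 contribute nothing and are skipped.
        chrom = w.alpha_c > 0
        intens = w.alpha_i > 0
        fills = {
            "rg": _fill_plane(channels.do_rg, cfg, "rg", 101) if chrom else None,
            "by": _fill_plane(channels.do_by, cfg, "by", 202) if chrom else None,
            "i": _fill_plane(channels.i_onoff, cfg, "i", 303) if intens else None,
        }
        o_rg = fills["rg"].surface if chrom else np.zeros_like(channels.do_rg)
        o_by = fills["by"].surface if chrom else np.zeros_like(channels.do_by)
        o_i = fills["i"].surface if intens else np.zeros_like(channels.i_onoff)
    else:
        # Ablation: no recurrent network; the "surfaces" are the raw
        # Laplacian channels, reducing the model to low/high-pass mixing.
        fills = {"rg": None, "by": None, "i": None}
        o_rg, o_by, o_i = channels.do_rg, channels.do_by, channels.i_onoff

    return PerceptionResult(
        p_rg=w.beta_c * channels.so_rg + w.alpha_c * o_rg,
        p_by=w.beta_c * channels.so_by + w.alpha_c * o_by,
        p_i=w.beta_i * channels.i_lpf + w.alpha_i * o_i,
        opponent=opp,
        channels=channels,
        fill_results=fills,
    )


def perceive(
    img: np.ndarray, cfg: Optional[PerceptionConfig] = None, clip: bool = True
) -> np.ndarray:
    """Full model: perceived RGB image (clipped to [0, 1] at export)."""
    res = perceive_channels(img, cfg)
    perceived = OpponentImage(rg=res.p_rg, by=res.p_by, intensity=res.p_i)
    return opponent_to_rgb(perceived, clip=clip)
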