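"""Reference scene fixtures.

``fig3_like`` is the package's canonical sub-noise experiment: three parabolic
arcs — two "smiles" and one "frown" (with y pointing down, a smile opens
toward smaller y) — on a 64 x 64 raster with additive Gaussian noise at an
amplitude signal-to-noise ratio of 1/3, i.e. the signal peak is a third of
the noise sd.  The exact composition is configurable; every run report
records the fixture actually used.
"""

from __future__ import annotations

import numpy as np

from .engine import EngineConfig
from .scenes import ArcSpec, SceneSpec

__all__ = ["fig3_like", "fig3_engine_config", "PRESETS"]

FIG3_SNR = 1.0 / 3.0


def fig3_like(seed: int = 0, snr: float = FIG3_SNR, noise_sigma: float = 1.0) -> SceneSpec:
    """Three parabolic arcs (smile, frown, smile) on a 64 x 64 raster,
    signal below noise (amplitude SNR defaults to 1/3)."""
    smile = np.pi  # opens toward -y: ends sit above the vertex on screen
    frown = 0.0
    arcs = (
        ArcSpec(18.0, 18.0, 0.05, smile - 0.15, 16.0, 3.0),
        ArcSpec(46.0, 27.0, 0.05, frown + 0.12, 16.0, 3.0),
        ArcSpec(32.0, 56.0, 0.05, smile + 0.10, 16.0, 3.0),
    )
    return SceneSpec(
        domain_width=64.0,
        domain_height=64.0,
        arcs=arcs,
        signal_amplitude=snr * noise_sigma,
        noise_sigma=noise_sigma,
        seed=seed,
        name="fig3-like",
    )


def fig3_engine_config(seed: int = 0, **overrides) -> EngineConfig:
    """Engine defaults for the fig3-like raster: clutter + one vague blob
    start, structural adaptation on, annealed floors."""
    kwargs = dict(
        dt=1.0,
        convergence_tol=3e-6,
        max_iterations=130,
        anneal_factor=0.9,
        initial_vagueness=0.5,
        floor_min=9.0,  # transverse variance of the sought arcs (3.0^2)
        structure_penalty=0.35,
        structure_check_period=5,
        settle_iterations=25,
        adapt=True,
        greedy_growth=True,
        growth_components=5,
        seed=seed,
    )
    kwargs.update(overrides)
    return EngineConfig(**kwargs)


PRESETS = {"fig3-like": fig3_like}
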