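"""Run configuration with the framework's standard parameter defaults."""

from __future__ import annotations

from dataclasses import dataclass, field

from .tracking import TrackingParams

__all__ = ["RunConfig", "DEFAULTS"]

#: standard analysis defaults: tracking steps/curvature/step budget and
#: fibre threshold, subcortical blueprint threshold (0.1% of valid
#: streamlines), similarity threshold (0.5%), KL shift delta, and the
#: match-region percentile.
DEFAULTS = {
    "step_size": 0.5,
    "curvature_threshold": 80.0,
    "max_steps": 2000,
    "volume_fraction_threshold": 0.01,
    "subcortical_threshold": 0.001,
    "similarity_threshold": 0.005,
    "delta": 1e-6,
    "match_percentile": 7.0,
}


@dataclass
class RunConfig:
    step_size: float = DEFAULTS["step_size"]
    curvature_threshold: float = DEFAULTS["curvature_threshold"]
    max_steps: int = DEFAULTS["max_steps"]
    volume_fraction_threshold: float = DEFAULTS["volume_fraction_threshold"]
    streamlines_per_seed_voxel: int = 1000
    subcortical_threshold: float = DEFAULTS["subcortical_threshold"]
    similarity_threshold: float = DEFAULTS["similarity_threshold"]
    delta: float = DEFAULTS["delta"]
    match_percentile: float = DEFAULTS["match_percentile"]
    rng_seed: int = 0
    extras: dict = field(default_factory=dict)

    def tracking_params(self) -> TrackingParams:
        return TrackingParams(
            step_size=self.step_size,
            curvature_threshold=self.curvature_threshold,
            max_steps=self.max_steps,
            volume_fraction_threshold=self.volume_fraction_threshold,
            streamlines_per_seed_voxel=self.streamlines_per_seed_voxel,
            rng_seed=self.rng_seed,
        )
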