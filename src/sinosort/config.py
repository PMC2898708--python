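"""Pipeline configuration: validation, YAML loading, and hashing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclasses.dataclass
class PipelineConfig:
    """All tunable parameters of the simulate/estimate/reconstruct flow.

    Attributes
    ----------
    n_projections
        Number of projections N (manifold methods want N >= ~256).
    n_samples
        Detector samples S per projection; odd so a t=0 sample exists.
    grid_size
        Image grid P (pixels per side) for phantoms and reconstructions.
    seed
        Seed feeding every random draw (angles, phantom, noise).
    angle_sampling
        ``"random"``: i.i.d. uniform view angles; ``"uniform"``: exactly
        uniform angles in shuffled order (the acquisition protocol of the
        quantitative experiments).
    snr_db
        Additive Gaussian noise level in dB; ``None`` means noiseless.
    feature_mode
        ``"complex"`` (full-circle, default) or ``"magnitude"``
        (shift-invariant; folds view angles to a half turn).
    band_fraction
        Fraction of the Fourier band kept; 1.0 noiseless, 0.5 noisy.
    threshold
        Neighbor-graph distance threshold T; ``None`` picks the smallest
        connecting value automatically (times ``threshold_safety``).
    refine
        Uniformly redistribute sorted angles (assumes uniform true angles).
    filter_window
        FBP filter: ``"ramp"`` or ``"hann"`` (noisy data).
    n_ellipses
        Ellipse count of the built-in random phantom.
    """

    n_projections: int = 360
    n_samples: int = 299
    grid_size: int = 128
    seed: int = 0
    angle_sampling: str = "random"
    snr_db: float | None = None
    feature_mode: str = "complex"
    band_fraction: float = 1.0
    threshold: float | None = None
    threshold_safety: float = 1.1
    refine: bool = True
    filter_window: str = "ramp"
    n_ellipses: int = 6

    def __post_init__(self) -> None:
        if self.n_projections < 2:
            raise ValueError("n_projections must be >= 2")
        if self.n_samples < 3 or self.n_samples % 2 == 0:
            raise ValueError("n_samples must be odd and >= 3")
        if self.grid_size < 32:
            raise ValueError("grid_size must be >= 32")
        if self.angle_sampling not in ("random", "uniform"):
            raise ValueError("angle_sampling must be 'random' or 'uniform'")
        if self.feature_mode not in ("complex", "magnitude"):
            raise ValueError("feature_mode must be 'complex' or 'magnitude'")
        if not 0.0 < self.band_fraction <= 1.0:
            raise ValueError("band_fraction must be in (0, 1]")
        if self.threshold is not None and self.threshold <= 0:
            raise ValueError("threshold must be positive (or None for auto)")
        if self.threshold_safety < 1.0:
            raise ValueError("threshold_safety must be >= 1")
        if self.filter_window not in ("ramp", "hann"):
            raise ValueError("filter_window must be 'ramp' or 'hann'")
        if self.n_ellipses < 3:
            raise ValueError("n_ellipses must be >= 3")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Short stable digest recorded in every output header."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load from a YAML mapping; keyword overrides win over the file."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
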