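"""Pipeline configuration: defaults, flat key-value file loading, hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields, replace
from pathlib import Path

__all__ = ["PipelineConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the detection chain, with its default.

    Intensities refer to the internal [0, 1] representation; lengths
    are pixels (in scaled 256x256 window coordinates for the masking
    and tracing parameters).
    """

    # conditioning
    gaussian_sigma: float = 1.0  # denoising Gaussian, px
    stretch_low: float = 1.0  # percentile mapped to 0
    stretch_high: float = 99.0  # percentile mapped to 1
    body_blob_min_fraction: float = 0.01  # min body-blob size, image fraction
    canny_low: float = 0.1  # Canny hysteresis, gradient units
    canny_high: float = 0.3
    min_edge_length: int = 10  # px, Canny cleanup

    # segmentation
    bone_threshold: float = 0.6  # intensity cut for bone voxels
    min_bone_area: int = 300  # px^2, smallest region kept
    bone_close_radius: int = 12  # px, closing that keeps a fractured bone one region
    n_landmarks: int = 50  # boundary landmarks per bone

    # wavelet
    swt_levels: int = 3  # decomposition depth; details taken at this level
    detail_source: str = "coefficients"  # edge map: "coefficients" | "reconstructed"

    # masking (scaled-window px)
    mask_sigma: float = 2.0
    mask_dilation: int = 5
    mask_min_component_fraction: float = 0.005
    mask_border: int = 16  # px excluded at the scaled-window border
    detail_sigma: float = 2.0  # envelope smoothing of the detail magnitude
    mask_closing: int = 2  # closing radius bridging sub-ridge breaks in W_e

    # tracing / aggregation
    small_object_fraction: float = 0.01  # the 1%-of-window-area rule
    min_consecutive: int = 1  # fractured windows needed for a site

    def validate(self) -> None:
        if not 0 <= self.stretch_low < self.stretch_high <= 100:
            raise ValueError("stretch percentiles must satisfy 0 <= low < high <= 100")
        if not self.canny_low < self.canny_high:
            raise ValueError("canny_low must be < canny_high")
        if self.gaussian_sigma <= 0 or self.mask_sigma <= 0:
            raise ValueError("Gaussian sigmas must be > 0")
        if not 1 <= self.swt_levels <= 4:
            raise ValueError("swt_levels must be in 1..4")
        if self.detail_source not in {"coefficients", "reconstructed"}:
            raise ValueError("detail_source must be 'coefficients' or 'reconstructed'")
        if self.n_landmarks < 1:
            raise ValueError("n_landmarks must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None, **overrides) -> PipelineConfig:
    """Read a flat ``key = value`` file (# comments allowed).

    Unknown keys raise; every default is overridable.  Keyword
    arguments override file values.
    """
    values: dict = {}
    if path is not None:
        known = {f.name: f.type for f in fields(PipelineConfig)}
        casts = {f.name: type(getattr(PipelineConfig(), f.name)) for f in fields(PipelineConfig)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, raw = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            values[key] = casts[key](raw) if casts[key] is not bool else raw.lower() in {"1", "true", "yes"}
    values.update(overrides)
    cfg = replace(PipelineConfig(), **values)
    cfg.validate()
    return cfg


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash of the full configuration."""
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
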