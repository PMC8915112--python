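"""Pipeline configuration: one validated document for every stage default."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, field, fields
from pathlib import Path

import yaml

from .errors import ParameterError

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of the analysis pipeline in one place.

    Precedence when running the CLI: explicit flag > config file > these
    defaults.  ``audio_rate_hz`` is expected to be exactly 7x ``fps``
    (the recording hardware samples 7 audio samples per frame); other
    ratios are allowed but warned about, since the decimation factor is
    derived from the ratio.
    """

    fps: float = 3150.0
    audio_rate_hz: float = 22050.0
    grid: str = "coarse"  # coarse | full | a1:a2:step,b1:b2:step
    normalization: str = "unit-l1-nodc"
    levels: int = 64
    closure_eps_px: float = 0.5
    smooth_window: int | None = None
    threshold_fraction: float = 0.25
    margin_px: int = 10
    aggregate: str = "mean"
    seed: int = 0
    out_dir: str = "glottiseg_out"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.audio_rate_hz <= 0:
            raise ParameterError("rates must be positive")
        if self.normalization not in ("none", "unit-l1-nodc"):
            raise ParameterError(f"unknown normalization {self.normalization!r}")
        if self.levels < 1:
            raise ParameterError("levels must be >= 1")
        if abs(self.audio_rate_hz - 7 * self.fps) > 1e-6:
            log.warning(
                "audio rate %.1f Hz is not 7x the frame rate %.1f Hz; "
                "decimation uses the rounded ratio",
                self.audio_rate_hz,
                self.fps,
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def digest(self) -> str:
        """Short stable hash of the effective configuration."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def build_grid(self):
        from . import param_segmentation as ps

        if self.grid == "coarse":
            return ps.coarse_grid()
        if self.grid == "full":
            return ps.full_grid()
        try:
            a_spec, b_spec = self.grid.split(",")
            a1, a2, a_step = (int(v) for v in a_spec.split(":"))
            b1, b2, b_step = (int(v) for v in b_spec.split(":"))
        except ValueError as exc:
            raise ParameterError(
                f"grid spec {self.grid!r} is not 'coarse', 'full' or "
                "'a1:a2:step,b1:b2:step'"
            ) from exc
        alphas = [a for a in range(a1, a2 + 1, a_step) if a % 2 == 1]
        betas = list(range(b1, b2 + 1, b_step))
        return ps.parameter_grid(alphas, betas)
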