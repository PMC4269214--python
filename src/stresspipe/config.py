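"""Pipeline configuration.

One flat dataclass holds every tunable of the pipeline: class thresholds,
spectral band edges, artifact-filter tolerance, DBSCAN parameters, filter
coefficients and seeds. It round-trips through JSON so a run can be
reproduced from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # --- stress-class mapping -------------------------------------------
    #: self-report score <= low_threshold -> class 0; >= high_threshold -> 2
    low_threshold: float = 0.3
    high_threshold: float = 0.7

    # --- HRV extraction --------------------------------------------------
    #: fractional deviation from the previously retained beat above which an
    #: RR interval is discarded as an artifact
    artifact_threshold: float = 0.2
    #: histogram bin width for the geometric measures, ms (1/128 s)
    hist_bin_ms: float = 1000.0 / 128.0
    #: approximate-entropy embedding dimension and tolerance factor (r = factor * SDNN)
    apen_m: int = 2
    apen_r_factor: float = 0.2
    #: spectral analysis range and oversampling of the frequency grid
    f_min_hz: float = 0.01
    f_max_hz: float = 0.4
    oversampling: int = 4
    #: band edges in Hz: VLF 0.01-0.04, LF 0.04-0.15, HF 0.15-0.4
    vlf_band: tuple[float, float] = (0.01, 0.04)
    lf_band: tuple[float, float] = (0.04, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.4)
    #: minimum usable session length, seconds of beats
    min_session_s: float = 300.0

    # --- phone extraction ------------------------------------------------
    dbscan_eps_m: float = 100.0
    dbscan_min_pts: int = 5
    audio_chunk_ms: int = 50
    audio_seed: int = 0

    # --- modeling ---------------------------------------------------------
    #: ridge penalty of the multinomial logit (guards separable small-n fits)
    ridge: float = 1e-4
    #: long-term stress low-pass filter coefficient (max per-day change)
    filter_alpha: float = 0.1
    #: relative-slider gain: maximum fraction of the remaining range reachable
    slider_alpha: float = 0.75

    # --- selection / evaluation ------------------------------------------
    r_threshold: float = 0.8
    p_threshold: float = 0.01
    sfs_folds: int = 10
    min_improvement: float = 0.0
    #: a user needs at least this many labeled nights for a user-specific model
    min_nights: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.low_threshold < self.high_threshold < 1.0:
            raise ValueError("class thresholds must satisfy 0 < low < high < 1")
        if not 0.0 < self.filter_alpha <= 1.0:
            raise ValueError("filter_alpha must lie in (0, 1]")
        if not 0.0 < self.slider_alpha <= 1.0:
            raise ValueError("slider_alpha must lie in (0, 1]")
        self.vlf_band = tuple(self.vlf_band)  # type: ignore[assignment]
        self.lf_band = tuple(self.lf_band)  # type: ignore[assignment]
        self.hf_band = tuple(self.hf_band)  # type: ignore[assignment]

    # --- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("vlf_band", "lf_band", "hf_band"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)
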