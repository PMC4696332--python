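"""Pipeline configuration: preprocessing thresholds, search windows, band edges."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any


@dataclass
class PipelineConfig:
    """All tunables of the per-subject marker pipeline.

    epoch_length_s
        Epoch length in seconds; 2 s gives the 0.5 Hz spectral resolution
        the band math assumes.
    amp_threshold_uv / grad_threshold_uv
        Automated artifact rejection: an epoch is dropped when any channel
        exceeds the peak-to-peak amplitude threshold (µV) or the maximum
        absolute sample-to-sample step (µV/sample).
    iaf_search_hz
        Extended alpha range searched for the individual alpha frequency
        peak (inclusive endpoints).
    tf_floor_hz / tf_iaf_offset_hz
        The theta/alpha transition frequency is the power minimum in
        [max(tf_floor, IAF − tf_iaf_offset), IAF − 0.5] Hz.
    total_range_hz
        Normalisation range for relative power (half-open bin assignment).
    beta1/beta2/gamma
        Fixed high-frequency band edges.  beta1/beta2 lower edges are
        IAF-relative offsets; NOTE: these edges are a package default, not
        an anchored quantity — theta/gamma results depend on this choice.
    risk_rule
        'fixed-cutoff' (low < 1.0 ≤ middle < 1.17 ≤ high) or
        'cohort-tertile'.
    """

    epoch_length_s: float = 2.0
    amp_threshold_uv: float = 100.0
    grad_threshold_uv: float = 50.0
    iaf_search_hz: tuple[float, float] = (5.0, 14.0)
    tf_floor_hz: float = 4.0
    tf_iaf_offset_hz: float = 6.0
    total_range_hz: tuple[float, float] = (2.0, 45.0)
    beta1_offset_hz: tuple[float, float] = (2.0, 5.0)   # relative to IAF
    beta2_upper_hz: float = 30.0                        # beta2 = [IAF+5, 30)
    gamma_hz: tuple[float, float] = (30.0, 45.0)
    risk_rule: str = "fixed-cutoff"
    macroareas: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        kwargs = {}
        for key, val in d.items():
            if key not in cls.__dataclass_fields__:
                raise KeyError(f"unknown config key {key!r}")
            if isinstance(val, list):
                val = tuple(val)
            kwargs[key] = val
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from YAML or JSON."""
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
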