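"""Pipeline configuration with physical-range validation.

All thresholds and constants of the protocol live here with their
defaults; the configuration serialises losslessly to/from JSON so every
report can embed the exact values used.
"""
from __future__ import annotations

import json

from pydantic import BaseModel, Field, model_validator


class PipelineConfig(BaseModel):
    """Every tunable constant of the processing pipeline."""

    fs_imu: float = Field(500.0, gt=0, description="IMU sampling rate, Hz")
    fs_grf: float = Field(1000.0, gt=0, description="force-plate rate, Hz")
    k1: float = Field(2.33, ge=0, description="accelerometer gain, 1/s")
    k2: float = Field(7.44, ge=0, description="magnetometer gain, 1/s")
    sls_window: int = Field(10, ge=2, description="moving-SD window, samples")
    sls_static_samples: int = Field(1000, ge=100)
    sls_start_factor: float = Field(2.0, gt=0)
    sls_scale: float = Field(10.0, gt=0,
                             description="presentation factor on the SD rule")
    to_threshold: float = Field(-0.6, lt=0,
                                description="take-off threshold, rad/s²")
    la_threshold: float = Field(7.0, gt=0, description="landing jerk, m/s³")
    t_risk: float = Field(0.100, gt=0, description="risk window, s")
    refractory: float = Field(0.200, gt=0, description="event refractory, s")
    gyro_smooth: int = Field(9, ge=1, description="|gyro| smoothing, samples")
    acc_smooth: int = Field(81, ge=1, description="|acc| smoothing, samples")
    cmj_d2_window: int = Field(151, ge=5,
                               description="GRF 2nd-derivative window")
    cmj_onset_band: float = Field(50.0, gt=0, description="onset band, N")
    ellipse_coverage: float = Field(0.90, gt=0, lt=1)
    lsi_band: tuple[float, float] = (85.0, 115.0)
    mdc_z: float = Field(1.96, gt=0)
    flight_force_threshold: float = Field(5.0, ge=0,
                                          description="flight force, N")
    still_threshold: float = Field(0.0349, gt=0,
                                   description="gyro stillness SD, rad/s")
    seed: int = 0

    @model_validator(mode="after")
    def _band_ordered(self):
        lo, hi = self.lsi_band
        if not 0 <= lo < hi:
            raise ValueError(f"lsi_band must be increasing, got {self.lsi_band}")
        return self

    def to_json(self, path=None) -> str:
        text = json.dumps(self.model_dump(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "PipelineConfig":
        if hasattr(source, "read"):
            data = json.load(source)
        else:
            try:
                data = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    data = json.load(fh)
        return cls.model_validate(data)
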