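"""Shared result carrier for hypothesis tests."""

from __future__ import annotations

from dataclasses import dataclass, replace

from .calibration import CalibrationRecord, calibrate


@dataclass(frozen=True)
class TestResult:
    """A test statistic, its p-value, and optional evidence calibration."""

    statistic: float
    p: float
    method: str
    calibrated: CalibrationRecord | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p-value out of range: {self.p}")

    def with_calibration(self, prior_prob_real: float = 0.5) -> "TestResult":
        """Attach a BFB/FPR/p(H0) calibration record for this p-value."""
        p = min(max(self.p, 1e-300), 1.0 - 1e-16)  # calibration needs open interval
        return replace(self, calibrated=calibrate(p, prior_prob_real))
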