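"""Per-sample capture statistics and QC gating.

Summarizes how well a sample's sequencing covered the capture panel:
on-target read/base yield, mean depth, breadth of coverage, and the
fraction of targeted bases at >= 20-fold depth (the panel's working
sensitivity threshold for confident genotype calls).

Mean depth is computed from the per-base depth vector (post-deduplication
pileup), not as reads x read_length / target_size: duplicate removal and
soft-clipping make the naive quotient overstate usable depth, and the two
definitions disagree on real capture data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel_io import ValidationError

__all__ = ["CaptureStats", "QCThresholds", "QCFlag", "capture_stats", "qc_gate"]


@dataclass(frozen=True)
class CaptureStats:
    """Capture summary for one sample over the panel footprint."""

    on_target_reads: int
    read_length: int
    on_target_bases: int
    mean_depth: float
    fraction_ge_20x: float
    coverage_ge_1x: float

    def __post_init__(self):
        if not 0.0 <= self.fraction_ge_20x <= self.coverage_ge_1x <= 1.0:
            raise ValidationError(
                "expected 0 <= fraction_ge_20x <= coverage_ge_1x <= 1, got "
                f"{self.fraction_ge_20x} / {self.coverage_ge_1x}"
            )

    def to_dict(self) -> dict:
        return {
            "on_target_reads": self.on_target_reads,
            "read_length": self.read_length,
            "on_target_bases": self.on_target_bases,
            "mean_depth": self.mean_depth,
            "fraction_ge_20x": self.fraction_ge_20x,
            "coverage_ge_1x": self.coverage_ge_1x,
        }


def capture_stats(
    depth_vector, on_target_reads: int, read_length: int = 90
) -> CaptureStats:
    """Compute capture statistics from a per-base on-target depth vector.

    Parameters
    ----------
    depth_vector
        Depth at every targeted base (length = panel total_size).
    on_target_reads
        Reads mapped to the target region (post-filter).
    read_length
        Read length in bases; on_target_bases = reads x length.
    """
    depths = np.asarray(depth_vector, dtype=float)
    if depths.size == 0:
        raise ValidationError("empty target: depth vector has no entries")
    if np.any(depths < 0):
        raise ValidationError("negative depth in depth vector")
    if on_target_reads < 0 or read_length < 0:
        raise ValidationError("reads and read length must be non-negative")
    return CaptureStats(
        on_target_reads=int(on_target_reads),
        read_length=int(read_length),
        on_target_bases=int(on_target_reads) * int(read_length),
        mean_depth=float(depths.mean()),
        fraction_ge_20x=float(np.mean(depths >= 20)),
        coverage_ge_1x=float(np.mean(depths >= 1)),
    )


@dataclass(frozen=True)
class QCThresholds:
    """Gate minima. Defaults are the worst per-sample values the panel is
    expected to tolerate: 77.43x mean depth, 90.34% of bases >= 20x, 99.4%
    breadth. Boundaries are inclusive (a value exactly at the minimum passes)."""

    mean_depth: float = 77.43
    fraction_ge_20x: float = 0.9034
    coverage_ge_1x: float = 0.994


@dataclass(frozen=True)
class QCFlag:
    metric: str
    value: float
    threshold: float
    passed: bool


def qc_gate(stats: CaptureStats, thresholds: QCThresholds | None = None) -> list[QCFlag]:
    """Compare each statistic with its gate; returns one flag per metric."""
    th = thresholds or QCThresholds()
    checks = (
        ("mean_depth", stats.mean_depth, th.mean_depth),
        ("fraction_ge_20x", stats.fraction_ge_20x, th.fraction_ge_20x),
        ("coverage_ge_1x", stats.coverage_ge_1x, th.coverage_ge_1x),
    )
    return [QCFlag(m, v, t, v >= t) for m, v, t in checks]
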