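"""The pipeline's central observable: a leaf water-content time series."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WaterContentSeries"]


@dataclass(frozen=True)
class WaterContentSeries:
    """Leaf water content (wt%) sampled over a drying experiment.

    times_h are hours since irrigation stop, strictly increasing; ``light``
    flags whether the growth light was on at each sample.  A typical drying
    campaign samples every 25 minutes over 8-14 days.
    """

    times_h: np.ndarray
    water_wt_pct: np.ndarray
    light: np.ndarray
    plant_id: str = "plant"
    genotype: str = "wildtype"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        w = np.asarray(self.water_wt_pct, dtype=float)
        li = np.asarray(self.light, dtype=bool)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("series needs at least two samples")
        if w.shape != t.shape or li.shape != t.shape:
            raise ValueError("times, water and light arrays must align")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((w < 0) | (w > 100)):
            raise ValueError("water content must lie in [0, 100] wt%")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "water_wt_pct", w)
        object.__setattr__(self, "light", li)

    def __len__(self) -> int:
        return self.times_h.size

    @property
    def cadence_min(self) -> float:
        """Median sampling interval in minutes."""
        return float(np.median(np.diff(self.times_h)) * 60.0)

    def duration_days(self) -> float:
        return float((self.times_h[-1] - self.times_h[0]) / 24.0)
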