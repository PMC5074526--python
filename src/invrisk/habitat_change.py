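"""Suitable-area computation and baseline-to-future change metrics.

Areas are sums of latitude-dependent geodesic cell areas (km^2), not
cell counts.  Change between a baseline and a future classified map is
summarised as the absolute delta, the percent change and the
future/baseline ratio; when the baseline area is zero the relative
metrics are undefined (None) and ``new_habitat_flag`` records whether
habitat appeared from nothing -- the "no habitat now, habitat later"
case that matters most for horizon-scanning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import GridMismatchError, Layer

WhichClass = int | str  # 1, 2 or "suitable" (= classes 1 and 2)


def _class_mask(class_map: Layer, which_class: WhichClass) -> np.ndarray:
    vals = class_map.values
    if which_class == "suitable":
        return np.isfinite(vals) & (vals >= 1)
    if which_class in (0, 1, 2):
        return np.isfinite(vals) & (vals == which_class)
    raise ValueError(f"which_class must be 0, 1, 2 or 'suitable', got {which_class!r}")


def habitat_area(class_map: Layer, areas: Layer, which_class: WhichClass = 2) -> float:
    """Total km^2 of cells in the requested habitat class."""
    if class_map.spec != areas.spec:
        raise GridMismatchError("class map and area layer are on different grids")
    mask = _class_mask(class_map, which_class)
    return float(areas.values[mask].sum())


@dataclass
class HabitatChange:
    """Baseline/future suitable-area pair with derived change metrics."""

    area_baseline: float
    area_future: float

    @property
    def delta(self) -> float:
        return self.area_future - self.area_baseline

    @property
    def pct_change(self) -> float | None:
        if self.area_baseline == 0:
            return None
        return 100.0 * self.delta / self.area_baseline

    @property
    def ratio(self) -> float | None:
        if self.area_baseline == 0:
            return None
        return self.area_future / self.area_baseline

    @property
    def new_habitat_flag(self) -> bool:
        return self.area_baseline == 0 and self.area_future > 0

    def as_dict(self) -> dict:
        return {
            "area_baseline_km2": self.area_baseline,
            "area_future_km2": self.area_future,
            "delta_km2": self.delta,
            "pct_change": self.pct_change,
            "ratio": self.ratio,
            "new_habitat": self.new_habitat_flag,
        }


def change_metrics(
    baseline: Layer, future: Layer, areas: Layer, which_class: WhichClass = 2
) -> HabitatChange:
    """Change in habitat area of one class between two classified maps."""
    return HabitatChange(
        area_baseline=habitat_area(baseline, areas, which_class),
        area_future=habitat_area(future, areas, which_class),
    )
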