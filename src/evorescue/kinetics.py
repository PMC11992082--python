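"""Within-cycle growth statistics from OD600 kinetic curves.

Each curve is smoothed with a trailing 8-point moving average, then two
summary statistics are computed:

* yield, in doublings: ``log2(OD_f / OD_i)`` where OD_i and OD_f are the
  first and last smoothed readings of the cycle;
* threshold growth rate, in h^-1: ``ln(1.5) / t_thr`` where t_thr is the
  first time the smoothed curve reaches 1.5 × OD_i (linearly interpolated
  between samples).  On a noiseless exponential this returns the true
  Malthusian rate.  If the curve never reaches the threshold the rate is
  undefined (reported as missing, never coerced to 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .plate_io import DataError, KineticCurve, PlateLayout

__all__ = [
    "GrowthSummary",
    "smooth_kinetic",
    "compute_yield",
    "compute_growth_rate",
    "analyze_growth",
    "summarize_dose_response",
]

_LN_THRESHOLD_RATIO = math.log(1.5)


@dataclass
class GrowthSummary:
    """Per-well growth statistics for one cycle.

    growth_rate and t_thr are None when the smoothed curve never reaches
    the 1.5×OD_i threshold.
    """

    yield_doublings: float
    growth_rate: float | None
    od_i: float
    od_f: float
    threshold: float
    t_thr: float | None  # hours
    meta: PlateLayout

    def to_row(self) -> dict:
        return {
            "id": self.meta.id,
            "culture_type": self.meta.culture_type.value,
            "treatment": self.meta.treatment.value,
            "dose": self.meta.dose,
            "replicate": self.meta.replicate,
            "yield": self.yield_doublings,
            "growth_rate": self.growth_rate,
            "od_i": self.od_i,
            "od_f": self.od_f,
            "threshold": self.threshold,
            "t_thr": self.t_thr,
        }


def smooth_kinetic(curve: KineticCurve, window: int = 8) -> KineticCurve:
    """Trailing moving average over ``window`` points.

    Output has the same length and time axis as the input; at the left
    edge the window shrinks to the points available, so the first smoothed
    reading equals the first raw reading.
    """
    n = len(curve)
    if window < 1:
        raise DataError("window must be >= 1")
    if window > n:
        raise DataError(f"window {window} exceeds curve length {n}")
    if window == 1:
        return KineticCurve(curve.times, curve.od.copy(), curve.meta)
    cs = np.concatenate(([0.0], np.cumsum(curve.od)))
    idx = np.arange(n)
    lo = np.maximum(0, idx - window + 1)
    sm = (cs[idx + 1] - cs[lo]) / (idx + 1 - lo)
    return KineticCurve(curve.times, sm, curve.meta)


def compute_yield(curve: KineticCurve) -> tuple[float, float, float]:
    """(yield in doublings, OD_i, OD_f) from an already-smoothed curve."""
    od_i, od_f = float(curve.od[0]), float(curve.od[-1])
    if od_i <= 0 or od_f <= 0:
        raise DataError(
            f"yield undefined for nonpositive OD (od_i={od_i}, od_f={od_f}) "
            f"in {curve.meta.id!r}"
        )
    return math.log2(od_f / od_i), od_i, od_f


def compute_growth_rate(
    curve: KineticCurve,
) -> tuple[float | None, float, float | None]:
    """(growth rate h^-1, threshold, t_thr hours) from a smoothed curve.

    The threshold is 1.5 × the first smoothed reading; t_thr is the first
    threshold crossing, linearly interpolated between the bracketing
    samples.  Returns (None, threshold, None) when never reached.
    """
    od = curve.od
    od_i = float(od[0])
    if od_i <= 0:
        raise DataError(f"growth rate undefined for od_i <= 0 in {curve.meta.id!r}")
    threshold = 1.5 * od_i
    above = np.nonzero(od >= threshold)[0]
    if len(above) == 0:
        return None, threshold, None
    j = int(above[0])  # j >= 1 because od[0] = od_i < threshold
    t0, t1 = curve.times[j - 1], curve.times[j]
    y0, y1 = od[j - 1], od[j]
    t_thr_min = t0 + (threshold - y0) / (y1 - y0) * (t1 - t0)
    t_thr = (t_thr_min - curve.times[0]) / 60.0
    return _LN_THRESHOLD_RATIO / t_thr, threshold, t_thr


def analyze_growth(curve: KineticCurve, window: int = 8) -> GrowthSummary:
    """Smooth a raw curve and compute yield and threshold growth rate."""
    sm = smooth_kinetic(curve, window)
    y, od_i, od_f = compute_yield(sm)
    rate, threshold, t_thr = compute_growth_rate(sm)
    return GrowthSummary(y, rate, od_i, od_f, threshold, t_thr, curve.meta)


def summarize_dose_response(summaries: Iterable[GrowthSummary]) -> pd.DataFrame:
    """Per (culture_type, treatment, dose) location/dispersion statistics.

    Undefined growth rates are excluded from the location statistics but
    counted in ``n_undefined`` so slow groups are not silently thinned.
    """
    summaries = list(summaries)
    if not summaries:
        raise DataError("summarize_dose_response needs at least one summary")
    df = pd.DataFrame(
        {
            "culture_type": s.meta.culture_type.value,
            "treatment": s.meta.treatment.value,
            "dose": s.meta.dose,
            "growth_rate": s.growth_rate,
            "yield": s.yield_doublings,
        }
        for s in summaries
    )
    rows = []
    for (ct, tr, dose), sub in df.groupby(
        ["culture_type", "treatment", "dose"], sort=True
    ):
        rates = sub["yield"].to_numpy(), sub["growth_rate"].dropna().to_numpy()
        yields, defined = rates[0], rates[1]
        row = {
            "culture_type": ct,
            "treatment": tr,
            "dose": dose,
            "n": len(sub),
            "n_undefined": int(sub["growth_rate"].isna().sum()),
        }
        for name, vals in [("growth_rate", defined), ("yield", yields)]:
            if len(vals):
                q1, q3 = np.percentile(vals, [25, 75])
                row.update(
                    {
                        f"{name}_median": float(np.median(vals)),
                        f"{name}_mean": float(np.mean(vals)),
                        f"{name}_sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                        f"{name}_iqr": float(q3 - q1),
                    }
                )
            else:
                row.update(
                    {
                        f"{name}_median": np.nan,
                        f"{name}_mean": np.nan,
                        f"{name}_sd": np.nan,
                        f"{name}_iqr": np.nan,
                    }
                )
        rows.append(row)
    return pd.DataFrame(rows)
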