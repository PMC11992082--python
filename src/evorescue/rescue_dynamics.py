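"""Per-population U-shaped rescue metrics across serial transfers.

A stressed population that escapes extinction traces a U-shaped density
trajectory: decline after stress onset, then recovery once an adapted
lineage expands.  From each end-of-cycle OD600 trajectory this module
derives:

* rescue transfer — the first transfer after stress onset at which the
  (window-3 smoothed) trajectory switches from a declining to an
  increasing trend (first positive first-difference); undefined if the
  trajectory never turns upward;
* maximum recovery rate — the largest positive per-transfer OD change
  after stress onset, on the smoothed trajectory;
* survival — whether the median raw OD over the last ``tail`` transfers
  strictly exceeds an extinction threshold (default 0.02, just above
  blank-level noise);
* normalized final size — median raw OD of the last three transfers,
  divided by the median final-transfer OD of same-treatment prototroph
  reference populations.

Trend metrics use the smoothed trajectory; survival and final size use
raw values so thresholding and normalization are not distorted by the
shrunken edge windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .plate_io import DataError, PlateLayout, TransferTrajectory, Treatment

__all__ = [
    "RescueMetrics",
    "smooth_transfers",
    "detect_rescue_transfer",
    "max_recovery_rate",
    "classify_survival",
    "final_size_normalized",
    "compute_rescue_metrics",
    "summarize_rescue",
]

DEFAULT_EXTINCTION_THRESHOLD = 0.02


@dataclass
class RescueMetrics:
    """Derived rescue quantities for one population.

    rescue_transfer and max_recovery_rate are None when the trajectory
    never turns upward / has no positive post-stress step.
    final_size_normalized is None when no reference populations exist.
    """

    rescue_transfer: int | None
    max_recovery_rate: float | None
    survived: bool
    final_size_normalized: float | None
    meta: PlateLayout

    def to_row(self) -> dict:
        return {
            "id": self.meta.id,
            "culture_type": self.meta.culture_type.value,
            "treatment": self.meta.treatment.value,
            "dose": self.meta.dose,
            "replicate": self.meta.replicate,
            "rescue_transfer": self.rescue_transfer,
            "max_recovery_rate": self.max_recovery_rate,
            "survived": self.survived,
            "final_size_normalized": self.final_size_normalized,
        }


def smooth_transfers(traj: TransferTrajectory, window: int = 3) -> TransferTrajectory:
    """Centered moving average with shrinking windows at the edges."""
    n = len(traj)
    if window < 1:
        raise DataError("window must be >= 1")
    if window > n:
        raise DataError(f"window {window} exceeds trajectory length {n}")
    if window == 1:
        return TransferTrajectory(traj.transfers, traj.od.copy(),
                                  traj.stress_start, traj.meta)
    left, right = (window - 1) // 2, window // 2
    cs = np.concatenate(([0.0], np.cumsum(traj.od)))
    idx = np.arange(n)
    lo = np.maximum(0, idx - left)
    hi = np.minimum(n, idx + right + 1)
    sm = (cs[hi] - cs[lo]) / (hi - lo)
    return TransferTrajectory(traj.transfers, sm, traj.stress_start, traj.meta)


def _post_stress_diffs(traj: TransferTrajectory) -> tuple[np.ndarray, np.ndarray]:
    """First differences od[t] - od[t-1] for transfers t > stress_start."""
    n, ss = len(traj), traj.stress_start
    if n < ss + 2:
        raise DataError(
            f"trajectory {traj.meta.id!r} too short ({n}) for stress_start {ss}"
        )
    # transfers are 1-based: transfer t sits at index t-1
    t_idx = np.arange(ss, n)  # indices of transfers stress_start+1 .. n
    return traj.transfers[t_idx], traj.od[t_idx] - traj.od[t_idx - 1]


def detect_rescue_transfer(traj: TransferTrajectory) -> int | None:
    """First post-stress transfer where the smoothed trend turns positive.

    Expects an already-smoothed trajectory.  Scanning left to right, the
    first transfer t > stress_start with od[t] > od[t-1] is the rescue
    transfer (every earlier post-stress step was non-increasing, so this
    is the declining-to-increasing trend change; a trajectory already
    rising at the first evaluable step counts as rescued there).  Ties
    (zero difference) are non-increasing and do not trigger rescue.
    Returns None if the trajectory never turns upward.
    """
    transfers, diffs = _post_stress_diffs(traj)
    pos = np.nonzero(diffs > 0)[0]
    return int(transfers[pos[0]]) if len(pos) else None


def max_recovery_rate(traj: TransferTrajectory) -> float | None:
    """Largest positive per-transfer OD change after stress onset.

    Expects an already-smoothed trajectory.  Returns None when no
    post-stress difference is positive.
    """
    _, diffs = _post_stress_diffs(traj)
    m = float(diffs.max())
    return m if m > 0 else None


def classify_survival(
    traj: TransferTrajectory,
    extinction_threshold: float = DEFAULT_EXTINCTION_THRESHOLD,
    tail: int = 3,
) -> bool:
    """Survived iff median raw OD of the last ``tail`` transfers > threshold.

    Strict inequality: a population sitting exactly at the threshold is
    classified extinct.
    """
    if tail < 1 or tail > len(traj):
        raise DataError(f"tail {tail} outside 1..{len(traj)}")
    return bool(np.median(traj.od[-tail:]) > extinction_threshold)


def final_size_normalized(
    traj: TransferTrajectory,
    reference: Sequence[TransferTrajectory],
    tail: int = 3,
) -> float:
    """Tail-median OD relative to the reference populations' final OD.

    Numerator: median raw OD of the last ``tail`` transfers of ``traj``.
    Denominator: median raw OD at the final transfer across ``reference``
    (typically same-treatment prototroph monocultures).
    """
    if not reference:
        raise DataError("final_size_normalized requires a nonempty reference set")
    T = len(traj)
    for r in reference:
        if len(r) != T:
            raise DataError("reference trajectories must have the same length")
    ref_med = float(np.median([r.od[-1] for r in reference]))
    if ref_med == 0:
        raise DataError("reference final-transfer median OD is zero")
    return float(np.median(traj.od[-tail:])) / ref_med


def compute_rescue_metrics(
    trajectories: Iterable[TransferTrajectory],
    reference: Mapping[Treatment, Sequence[TransferTrajectory]] | Sequence[TransferTrajectory] | None = None,
    window: int = 3,
    extinction_threshold: float = DEFAULT_EXTINCTION_THRESHOLD,
    tail: int = 3,
) -> list[RescueMetrics]:
    """Full per-population rescue metrics.

    ``reference`` maps each treatment to its prototroph reference
    trajectories (or is a single sequence applied to all treatments, or
    None to skip final-size normalization).  Trend metrics are computed on
    the window-smoothed trajectory; survival and final size on raw values.
    """
    out = []
    for traj in trajectories:
        sm = smooth_transfers(traj, window)
        if reference is None:
            ref: Sequence[TransferTrajectory] | None = None
        elif isinstance(reference, Mapping):
            ref = reference.get(traj.meta.treatment)
        else:
            ref = reference
        out.append(
            RescueMetrics(
                rescue_transfer=detect_rescue_transfer(sm),
                max_recovery_rate=max_recovery_rate(sm),
                survived=classify_survival(traj, extinction_threshold, tail),
                final_size_normalized=(
                    final_size_normalized(traj, ref, tail) if ref else None
                ),
                meta=traj.meta,
            )
        )
    return out


def summarize_rescue(metrics: Iterable[RescueMetrics]) -> pd.DataFrame:
    """Per-treatment medians/IQRs and survival counts.

    Undefined metric values are excluded from location statistics and
    counted in the ``n_*_defined`` columns.
    """
    metrics = list(metrics)
    if not metrics:
        raise DataError("summarize_rescue needs at least one metric")
    df = pd.DataFrame([m.to_row() for m in metrics])
    rows = []
    for tr, sub in df.groupby("treatment", sort=True):
        row = {"treatment": tr, "n": len(sub), "n_survived": int(sub["survived"].sum())}
        for name in ("rescue_transfer", "max_recovery_rate", "final_size_normalized"):
            vals = sub[name].dropna().to_numpy(dtype=float)
            row[f"n_{name}_defined"] = len(vals)
            if len(vals):
                q1, q3 = np.percentile(vals, [25, 75])
                row[f"{name}_median"] = float(np.median(vals))
                row[f"{name}_iqr"] = float(q3 - q1)
            else:
                row[f"{name}_median"] = np.nan
                row[f"{name}_iqr"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
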