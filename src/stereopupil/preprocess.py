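"""Two-step artifact filtering of recorded pupil time series.

Step 1 removes every sample whose outline confidence (the minimum over the
two cameras) is strictly below 1 — this robustly catches eye blinks, whose
occluded fits cannot reach full boundary contrast.  Step 2 screens stereo
matching-point errors: the difference of the ellipse axis ratios between
the two cameras is constant up to noise for a well-matched rig, so samples
whose axis-ratio difference deviates from the series median by more than
``k`` robust standard deviations (1.4826 x MAD) are removed.  Filters are
non-destructive: removed records keep their raw values and carry a removal
reason, so the raw series is always recoverable.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

REASON_NONE = "none"
REASON_CONFIDENCE = "confidence"
REASON_AXIS_RATIO = "axis_ratio_outlier"

#: confidences are compared after rounding, so CSV round trips at 6-decimal
#: formatting cannot flip the strict threshold
_CONF_DECIMALS = 6


class PupilSeries:
    """An ordered pupil measurement series with removal bookkeeping.

    Wraps a DataFrame with (at least) ``frame_count`` and ``diameter_mm``
    columns, per-camera ``outline_confidence_*`` / ``axis_ratio_*`` columns
    for stereo data, and the filter state (``removed``, ``removal_reason``).
    """

    def __init__(self, df: pd.DataFrame, sampling_rate: float | None = None):
        df = df.copy().reset_index(drop=True)
        if "removed" not in df:
            df["removed"] = False
        if "removal_reason" not in df:
            df["removal_reason"] = REASON_NONE
        if "frame_count" in df:
            fc = df["frame_count"].to_numpy()
            if len(fc) > 1 and not np.all(np.diff(fc) > 0):
                raise ValueError("frame counts must be strictly increasing")
        self.df = df
        self.sampling_rate = sampling_rate

    # -- construction -----------------------------------------------------
    @classmethod
    def from_simulated(cls, seq, sampling_rate: float | None = None) -> "PupilSeries":
        """Build a series from a synthetic stereo sequence (with truth)."""
        diam = seq.measured_diameters()
        df = pd.DataFrame(
            {
                "frame_count": seq.frame_counts,
                "diameter_mm": diam,
                "diameter_px_main": [f.diameter_px for f in seq.fits_main],
                "diameter_px_secondary": [f.diameter_px for f in seq.fits_secondary],
                "outline_confidence_main": [
                    f.outline_confidence for f in seq.fits_main
                ],
                "outline_confidence_secondary": [
                    f.outline_confidence for f in seq.fits_secondary
                ],
                "axis_ratio_main": [f.axis_ratio for f in seq.fits_main],
                "axis_ratio_secondary": [f.axis_ratio for f in seq.fits_secondary],
                "label": seq.labels,
            }
        )
        return cls(df, sampling_rate=sampling_rate)

    @property
    def is_stereo(self) -> bool:
        return "axis_ratio_secondary" in self.df and (
            self.df["axis_ratio_secondary"].notna().any()
        )

    @property
    def surviving(self) -> pd.DataFrame:
        return self.df[~self.df["removed"]]

    def copy(self) -> "PupilSeries":
        return PupilSeries(self.df, self.sampling_rate)

    def __len__(self):
        return len(self.df)

    def _times_s(self) -> np.ndarray:
        if "timestamp_ms" in self.df and self.df["timestamp_ms"].notna().all():
            return self.df["timestamp_ms"].to_numpy(dtype=float) / 1000.0
        rate = self.sampling_rate or 1.0
        return self.df["frame_count"].to_numpy(dtype=float) / rate


def filter_outline_confidence(
    series: PupilSeries, threshold: float = 1.0
) -> PupilSeries:
    """Mark removed every record with outline confidence strictly below 1.

    The minimum of the two cameras' confidences governs; values are clamped
    to [0, 1] and rounded to 6 decimals before the strict comparison.
    """
    out = series.copy()
    if len(out) == 0:
        return out
    conf = out.df["outline_confidence_main"].to_numpy(dtype=float)
    if "outline_confidence_secondary" in out.df:
        sec = out.df["outline_confidence_secondary"].to_numpy(dtype=float)
        conf = np.fmin(conf, sec)
    conf = np.round(np.clip(conf, 0.0, 1.0), _CONF_DECIMALS)
    hit = (conf < threshold) & ~out.df["removed"].to_numpy()
    out.df.loc[hit, "removed"] = True
    out.df.loc[hit, "removal_reason"] = REASON_CONFIDENCE
    return out


def filter_axis_ratio_outliers(series: PupilSeries, k: float = 3.0) -> PupilSeries:
    """Remove strong outliers of the inter-camera axis-ratio difference.

    On the surviving records, ``dr = axis_ratio_main - axis_ratio_secondary``
    is screened with a median +/- k robust-SD rule (robust SD =
    1.4826 x MAD).  A zero MAD degenerates to removing every record whose
    ``dr`` differs from the median at all.  Mono series are returned
    unchanged with a warning.
    """
    out = series.copy()
    if len(out) == 0:
        return out
    if not out.is_stereo:
        warnings.warn(
            "axis-ratio filtering needs stereo data; series left unchanged",
            stacklevel=2,
        )
        return out
    alive = ~out.df["removed"].to_numpy()
    dr = (
        out.df["axis_ratio_main"].to_numpy(dtype=float)
        - out.df["axis_ratio_secondary"].to_numpy(dtype=float)
    )
    # outlier statistics pool every record that passed the confidence step
    # (including previously axis-flagged ones), so re-application computes
    # the identical threshold and the filter is idempotent
    pool = (out.df["removal_reason"].to_numpy() != REASON_CONFIDENCE)
    med = float(np.median(dr[pool]))
    mad = float(np.median(np.abs(dr[pool] - med)))
    if mad == 0.0:
        hit = alive & (dr != med)
    else:
        hit = alive & (np.abs(dr - med) > k * 1.4826 * mad)
    out.df.loc[hit, "removed"] = True
    out.df.loc[hit, "removal_reason"] = REASON_AXIS_RATIO
    return out


def two_step_preprocess(
    series: PupilSeries, threshold: float = 1.0, k: float = 3.0
) -> PupilSeries:
    """Confidence filter followed by the axis-ratio outlier filter.

    Idempotent: re-applying to its own output removes nothing further
    (outlier statistics are computed on surviving records only).
    """
    return filter_axis_ratio_outliers(
        filter_outline_confidence(series, threshold=threshold), k=k
    )


def invalid_data_rate(raw: PupilSeries, filtered: PupilSeries) -> float:
    """Percentage of raw samples removed by filtering."""
    if len(raw) == 0:
        raise ValueError("invalid data rate is undefined for an empty series")
    if len(filtered) != len(raw):
        raise ValueError("filtered series must derive from the raw series")
    removed = int(filtered.df["removed"].sum())
    return 100.0 * removed / len(raw)


def steady_state_mean(series: PupilSeries, window_s: float = 5.0) -> float:
    """Mean surviving diameter over the trailing ``window_s`` seconds.

    Returns NaN when no surviving values fall inside the window.
    """
    if len(series) == 0 or window_s <= 0:
        return float("nan")
    t = series._times_s()
    in_window = t > t[-1] - window_s
    alive = ~series.df["removed"].to_numpy()
    vals = series.df["diameter_mm"].to_numpy(dtype=float)[in_window & alive]
    vals = vals[np.isfinite(vals)]
    return float(np.mean(vals)) if vals.size else float("nan")


def interpolate_gaps(series: PupilSeries, max_gap_s: float) -> PupilSeries:
    """Linearly interpolate diameters over short removed/missing spans.

    Spans no longer than ``max_gap_s`` get a ``diameter_mm_interp`` value
    interpolated between the neighbouring surviving samples; longer spans
    (e.g. after a detector breakdown) stay missing.
    """
    out = series.copy()
    if len(out) == 0:
        out.df["diameter_mm_interp"] = pd.Series(dtype=float)
        return out
    t = out._times_s()
    vals = out.df["diameter_mm"].to_numpy(dtype=float).copy()
    vals[out.df["removed"].to_numpy()] = np.nan
    interp = vals.copy()
    missing = ~np.isfinite(vals)
    if missing.any() and (~missing).any():
        idx = np.flatnonzero(missing)
        # contiguous missing runs
        splits = np.flatnonzero(np.diff(idx) > 1)
        for run in np.split(idx, splits + 1):
            i0, i1 = run[0] - 1, run[-1] + 1
            if i0 < 0 or i1 >= len(vals):
                continue
            if t[i1] - t[i0] > max_gap_s:
                continue
            interp[run] = np.interp(t[run], [t[i0], t[i1]], [vals[i0], vals[i1]])
    out.df["diameter_mm_interp"] = interp
    return out


def filter_report(raw: PupilSeries, filtered: PupilSeries) -> str:
    """Human-readable summary of removals per reason."""
    counts = filtered.df["removal_reason"].value_counts()
    lines = [
        f"total records:        {len(raw)}",
        f"removed (confidence): {int(counts.get(REASON_CONFIDENCE, 0))}",
        f"removed (axis ratio): {int(counts.get(REASON_AXIS_RATIO, 0))}",
        f"invalid data rate:    {invalid_data_rate(raw, filtered):.2f}%",
    ]
    return "\n".join(lines)
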