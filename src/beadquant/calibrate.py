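"""Two-segment log-log calibration, linear dynamic range and bead stability.

A serial titration of a biotinylated target against its capture-probe beads
gives, on log10-log10 axes, two straight lines: a proportional phase below a
saturation knot and a plateau above it.  The fit searches every observed
amount as a candidate knot (the knot point belongs to both segments), fits
ordinary least squares per side on per-amount replicate means, and keeps the
knot minimizing the total SSE; SSE ties break toward the larger knot, which
is the conservative (wider) claim for the linear range.  No continuity
constraint links the segments.

The linear dynamic range runs from the limit of detection (smallest measured
amount whose raw MFI exceeds mean + 3*SD of the background wells in every
replicate well — the conventional 3-sigma rule) up to the fitted knot.

Bead stability compares titrations repeated over days post-conjugation: the
retention at a day is the geometric mean over amounts of the MFI ratio to
the reference day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import quantify

__all__ = [
    "CalibrationCurve",
    "SegmentedFit",
    "LinearRange",
    "curve_from_plate",
    "fit_two_segment",
    "detect_linear_range",
    "assess_stability",
]


@dataclass
class CalibrationCurve:
    """Titration measurements for one bead region.

    ``points`` columns: amount (fmol), mfi (background-corrected), raw_mfi,
    day, replicate.  ``background_mfis`` holds the raw MFIs of the no-target
    wells for the same region.
    """

    points: pd.DataFrame
    background_mfis: np.ndarray | None = None


@dataclass
class SegmentedFit:
    """Two-line fit in (log10 amount, log10 MFI) space."""

    knot: float
    slope_low: float
    slope_high: float
    intercept_low: float
    intercept_high: float
    r2: float
    sse: float
    n_low: int
    n_high: int


@dataclass
class LinearRange:
    lower_fmol: float  # limit of detection
    upper_fmol: float  # saturation onset (= fitted knot)


def curve_from_plate(plate, region: int | None = None, min_events: int = 100) -> CalibrationCurve:
    """Build a calibration curve from a simulated (or read-in) plate.

    Runs the MFI + background-correction pipeline and joins the per-well
    target amounts and days recorded in the plate truth block / layout.
    """
    region = region if region is not None else plate.truth["region"]
    mfis = quantify.compute_mfi(plate.events, min_events=min_events)
    corrected, model = quantify.background_correct(mfis, plate.layout)
    sub = corrected[corrected["region"] == region].copy()
    amounts = plate.truth["amounts"]
    well_day = plate.truth.get("well_day", {})
    sub["amount"] = sub["sample_id"].map(amounts)
    if sub["amount"].isna().any():
        missing = sorted(sub.loc[sub["amount"].isna(), "sample_id"].unique())
        raise ValueError(f"no target amount known for sample(s) {missing}")
    sub["day"] = sub["well"].map(lambda w: well_day.get(w, 0))
    points = sub.rename(columns={"net": "mfi", "mfi": "raw_mfi"})[
        ["amount", "mfi", "raw_mfi", "day", "replicate"]
    ].reset_index(drop=True)
    merged = mfis.merge(plate.layout, on="well")
    bg = merged[(merged["role"] == "background") & (merged["region"] == region) & (merged["qc"] == "")]
    return CalibrationCurve(points=points, background_mfis=bg["mfi"].to_numpy(float))


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line; returns (slope, intercept, sse)."""
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return float(slope), float(intercept), float(resid @ resid)


def fit_two_segment(curve: CalibrationCurve, min_per_side: int = 3) -> SegmentedFit:
    """Fit the two-segment log-log calibration on per-amount replicate means.

    Candidate knots are the observed amounts leaving at least
    ``min_per_side`` points per side (the knot point is shared by both
    segments).  Requires >= 6 distinct amounts and positive corrected MFIs.
    """
    pts = curve.points
    means = pts.groupby("amount")["mfi"].mean().sort_index()
    if len(means) < 2 * min_per_side:
        raise ValueError(f"need >= {2 * min_per_side} distinct amounts, got {len(means)}")
    if (means <= 0).any():
        bad = means[means <= 0].index.tolist()
        raise ValueError(f"nonpositive corrected MFI at amount(s) {bad}")
    x = np.log10(means.index.to_numpy(float))
    y = np.log10(means.to_numpy(float))
    n = len(x)

    fits = []
    for i in range(min_per_side - 1, n - min_per_side + 1):
        lo_s, lo_b, lo_sse = _ols(x[: i + 1], y[: i + 1])
        hi_s, hi_b, hi_sse = _ols(x[i:], y[i:])
        fits.append((i, lo_s, lo_b, hi_s, hi_b, lo_sse + hi_sse))
    best_sse = min(f[-1] for f in fits)
    tol = 1e-9 * (1.0 + best_sse)
    # ties toward the larger knot
    i, lo_s, lo_b, hi_s, hi_b, sse = max(
        (f for f in fits if f[-1] <= best_sse + tol), key=lambda f: f[0]
    )
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    return SegmentedFit(
        knot=float(means.index[i]),
        slope_low=lo_s,
        slope_high=hi_s,
        intercept_low=lo_b,
        intercept_high=hi_b,
        r2=float(r2),
        sse=float(sse),
        n_low=i + 1,
        n_high=n - i,
    )


def detect_linear_range(
    curve: CalibrationCurve, fit: SegmentedFit, background_mfis=None
) -> LinearRange:
    """Linear dynamic range: 3-sigma LOD up to the fitted knot.

    The LOD is the smallest measured amount whose *raw* MFI exceeds
    mean(background) + 3*SD(background) in every replicate well.
    """
    bg = np.asarray(
        background_mfis if background_mfis is not None else curve.background_mfis, dtype=float
    )
    if bg.size == 0:
        raise ValueError("no background well MFIs available")
    threshold = bg.mean() + 3.0 * (bg.std(ddof=1) if bg.size > 1 else 0.0)
    pts = curve.points
    for amount in sorted(pts["amount"].unique()):
        raw = pts.loc[pts["amount"] == amount, "raw_mfi"]
        if (raw > threshold).all():
            if amount >= fit.knot:
                break
            return LinearRange(lower_fmol=float(amount), upper_fmol=float(fit.knot))
    raise ValueError(
        f"below detection: no amount under the knot exceeds the background "
        f"threshold {threshold:.3g} in every replicate well"
    )


def assess_stability(
    curves_by_day: dict[int, CalibrationCurve],
    reference_day: int = 0,
    stable_threshold: float = 0.90,
) -> pd.DataFrame:
    """Signal retention per day relative to the reference day.

    retention(day) = geometric mean over amounts of
    meanMFI(day, amount) / meanMFI(reference_day, amount); a day is flagged
    stable when retention >= ``stable_threshold``.  All days must share the
    amount grid; amounts with a nonpositive mean on either day are excluded
    from the geometric mean.
    """
    if reference_day not in curves_by_day:
        raise ValueError(f"reference day {reference_day} not among {sorted(curves_by_day)}")

    def per_amount_means(curve: CalibrationCurve) -> pd.Series:
        return curve.points.groupby("amount")["mfi"].mean().sort_index()

    ref = per_amount_means(curves_by_day[reference_day])
    rows = []
    for day in sorted(curves_by_day):
        means = per_amount_means(curves_by_day[day])
        if not np.array_equal(means.index.to_numpy(), ref.index.to_numpy()):
            raise ValueError(f"amount grid of day {day} differs from reference day")
        ratio = (means / ref).to_numpy(float)
        ratio = ratio[(means.to_numpy() > 0) & (ref.to_numpy() > 0)]
        if ratio.size == 0:
            raise ValueError(f"no positive MFI pairs between day {day} and reference")
        ret = float(np.exp(np.mean(np.log(ratio))))
        rows.append((day, ret, ret >= stable_threshold))
    return pd.DataFrame(rows, columns=["day", "retention", "stable"])
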