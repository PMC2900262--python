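"""Core data-processing pipeline for bead-array readings.

Stages, in the order they are applied:

1. :func:`compute_mfi` — per (well, region) median of event fluorescence;
   groups with fewer than ``min_events`` beads (default 100) are flagged
   ``low_count`` and excluded downstream.
2. :func:`background_correct` — subtract, per bead region, the mean MFI of
   the no-target wells; readings below that mean are flagged
   ``below_background`` (marked, never silently dropped).
3. :func:`spike_normalize` — per well, divide each miRNA's net MFI by the
   net MFI of the spike-in control bead; the spike was added in a known
   amount before labeling, so this ratio cancels labeling efficiency and any
   per-well gain.
4. :func:`summarize_expression` — mean/SD over replicate wells, test/reference
   ratio, log2 transform, quadrature propagation of relative SDs, and a
   Student-t 95% CI on the normalized scale.

Mismatch specificity (:func:`specificity_score`) reports each mismatch
probe's normalized signal as a percentage of the perfect-match probe, with a
one-sided Welch test of the decrease.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BackgroundModel",
    "compute_mfi",
    "background_correct",
    "spike_normalize",
    "summarize_expression",
    "specificity_score",
]

QC_OK = ""
QC_LOW_COUNT = "low_count"
QC_BELOW_BACKGROUND = "below_background"


@dataclass
class BackgroundModel:
    """Per-region mean/SD of background-well MFIs."""

    stats: pd.DataFrame  # region, bg_mean, bg_sd, n_wells

    def mean(self, region: int) -> float:
        return float(self.stats.set_index("region").loc[region, "bg_mean"])

    def sd(self, region: int) -> float:
        return float(self.stats.set_index("region").loc[region, "bg_sd"])


def compute_mfi(events: pd.DataFrame, min_events: int = 100) -> pd.DataFrame:
    """Median fluorescence intensity per (well, region).

    Returns columns ``well, region, mfi, n_events, qc``; groups with fewer
    than ``min_events`` events carry the ``low_count`` flag.
    """
    if events.empty:
        raise ValueError("empty event table")
    g = events.groupby(["well", "region"], sort=True)["fluorescence"]
    out = g.agg(mfi="median", n_events="count").reset_index()
    out["qc"] = np.where(out["n_events"] < min_events, QC_LOW_COUNT, QC_OK)
    return out


def _merge_layout(mfis: pd.DataFrame, layout: pd.DataFrame) -> pd.DataFrame:
    merged = mfis.merge(layout, on="well", how="left", validate="many_to_one")
    unknown = merged["role"].isna()
    if unknown.any():
        wells = sorted(merged.loc[unknown, "well"].unique())
        raise ValueError(f"wells missing from layout: {wells}")
    return merged


def background_correct(
    mfis: pd.DataFrame, layout: pd.DataFrame
) -> tuple[pd.DataFrame, BackgroundModel]:
    """Subtract the per-region mean background-well MFI.

    Returns the corrected table (adds ``net`` and extends ``qc``) for
    non-background wells, and the fitted :class:`BackgroundModel`.  Readings
    smaller than the background mean are flagged ``below_background``.
    """
    merged = _merge_layout(mfis, layout)
    ok = merged["qc"] == QC_OK
    bg = merged[(merged["role"] == "background") & ok]
    regions = sorted(merged["region"].unique())
    missing = [r for r in regions if r not in set(bg["region"])]
    if missing:
        raise ValueError(f"no background wells for region(s) {missing}")
    stats_df = (
        bg.groupby("region")["mfi"]
        .agg(bg_mean="mean", bg_sd=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0, n_wells="count")
        .reset_index()
    )
    model = BackgroundModel(stats=stats_df)

    corrected = merged[merged["role"] != "background"].copy()
    means = stats_df.set_index("region")["bg_mean"]
    corrected["net"] = corrected["mfi"] - corrected["region"].map(means)
    below = (corrected["mfi"] < corrected["region"].map(means)) & (corrected["qc"] == QC_OK)
    corrected.loc[below, "qc"] = QC_BELOW_BACKGROUND
    return corrected.reset_index(drop=True), model


def spike_normalize(
    corrected: pd.DataFrame, spike_region: int, region_probe: dict | None = None
) -> pd.DataFrame:
    """Per-well miRNA/spike net-MFI ratio.

    Wells whose spike reading failed QC or has net <= 0 are excluded with a
    warning; if every well is excluded this is an error.  ``region_probe``
    optionally annotates rows with a ``probe_id`` column.
    """
    out_rows = []
    excluded = []
    for well, grp in corrected.groupby("well", sort=True):
        spike = grp[grp["region"] == spike_region]
        if len(spike) != 1 or spike.iloc[0]["qc"] != QC_OK or spike.iloc[0]["net"] <= 0:
            excluded.append(well)
            continue
        spike_net = float(spike.iloc[0]["net"])
        for _, row in grp[grp["region"] != spike_region].iterrows():
            if row["qc"] != QC_OK:
                continue
            out_rows.append(
                (well, row["sample_id"], row["role"], row["replicate"], int(row["region"]),
                 row["net"] / spike_net)
            )
    if excluded:
        warnings.warn(f"wells excluded (spike missing, flagged, or net <= 0): {excluded}")
    if not out_rows:
        raise ValueError("all wells excluded during spike normalization")
    out = pd.DataFrame(
        out_rows, columns=["well", "sample_id", "role", "replicate", "region", "norm"]
    )
    if region_probe is not None:
        out["probe_id"] = out["region"].map(lambda r: region_probe.get(r) or region_probe.get(str(r)))
    return out


def summarize_expression(
    normalized: pd.DataFrame,
    reference_sample: str,
    region_probe: dict | None = None,
) -> pd.DataFrame:
    """Replicate summary and log2 relative expression vs the reference sample.

    Per (sample, miRNA): mean/SD of per-well normalized values; the
    test/reference ratio R with relative SDs combined in quadrature
    (relSD_R = sqrt(relSD_s^2 + relSD_ref^2)); log2_ratio = log2(R) with
    log2_sd = relSD_R / ln 2 (delta method); 95% CI = mean +/- t_{0.975,n-1}
    * SD/sqrt(n) on the normalized scale.  Samples with fewer than 2
    surviving wells are reported with missing SD/CI.
    """
    df = normalized.copy()
    if "probe_id" not in df.columns:
        if region_probe is None:
            raise ValueError("need probe_id column or a region_probe mapping")
        df["probe_id"] = df["region"].map(lambda r: region_probe.get(r) or region_probe.get(str(r)))
    summ = (
        df.groupby(["sample_id", "probe_id"])["norm"]
        .agg(norm_mfi_mean="mean", norm_mfi_sd=lambda x: x.std(ddof=1), n_wells="count")
        .reset_index()
    )
    ref = summ[summ["sample_id"] == reference_sample].set_index("probe_id")
    if ref.empty or (ref["n_wells"] < 2).any():
        raise ValueError(
            f"reference sample {reference_sample!r} needs >= 2 surviving wells per probe"
        )

    rows = []
    for _, r in summ.iterrows():
        m = r["probe_id"]
        mean_s, sd_s, n = r["norm_mfi_mean"], r["norm_mfi_sd"], int(r["n_wells"])
        mean_ref = float(ref.loc[m, "norm_mfi_mean"])
        sd_ref = float(ref.loc[m, "norm_mfi_sd"])
        n_ref = int(ref.loc[m, "n_wells"])
        if n >= 2 and mean_s > 0 and mean_ref > 0:
            rel_s = sd_s / mean_s
            rel_ref = sd_ref / mean_ref
            rel_r = float(np.hypot(rel_s, rel_ref))
            log2_ratio = float(np.log2(mean_s / mean_ref))
            log2_sd = rel_r / np.log(2)
            half = stats.t.ppf(0.975, n - 1) * sd_s / np.sqrt(n)
            ci_low, ci_high = mean_s - half, mean_s + half
        else:
            log2_ratio = float(np.log2(mean_s / mean_ref)) if mean_s > 0 and mean_ref > 0 else np.nan
            log2_sd = ci_low = ci_high = np.nan
            sd_s = np.nan if n < 2 else sd_s
        rows.append(
            (r["sample_id"], m, mean_s, sd_s, n, log2_ratio, log2_sd, ci_low, ci_high)
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "sample", "mirna", "norm_mfi_mean", "norm_mfi_sd", "n_wells",
            "log2_ratio", "log2_sd", "ci95_low", "ci95_high",
        ],
    )
    # RNU6B-style check not needed here; keep reference rows too (log2_ratio = 0)
    return out.sort_values(["mirna", "sample"]).reset_index(drop=True)


def specificity_score(
    normalized: pd.DataFrame, pm_probe: str, mm_probes: list[str]
) -> pd.DataFrame:
    """Mismatch-probe signal as % of the perfect-match probe.

    ``pct_of_pm = 100 * mean(norm_mm) / mean(norm_pm)`` over replicate wells,
    ``drop_pct = 100 - pct_of_pm``; p-value from a one-sided Welch two-sample
    t test of mm < pm.
    """
    if "probe_id" not in normalized.columns:
        raise ValueError("normalized table must carry a probe_id column")
    pm = normalized.loc[normalized["probe_id"] == pm_probe, "norm"].to_numpy(float)
    if pm.size == 0 or pm.mean() <= 0:
        raise ValueError(f"perfect-match probe {pm_probe!r} has no positive signal")
    rows = []
    for probe in mm_probes:
        mm = normalized.loc[normalized["probe_id"] == probe, "norm"].to_numpy(float)
        if mm.size == 0:
            raise ValueError(f"no measurements for probe {probe!r}")
        pct = 100.0 * mm.mean() / pm.mean()
        if mm.size > 1 and pm.size > 1:
            p = float(stats.ttest_ind(mm, pm, equal_var=False, alternative="less").pvalue)
        else:
            p = np.nan
        rows.append((probe, pct, 100.0 - pct, p, int(mm.size)))
    return pd.DataFrame(rows, columns=["probe_id", "pct_of_pm", "drop_pct", "p_value", "n"])
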