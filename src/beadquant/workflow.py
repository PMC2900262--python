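"""End-to-end workflows over the simulated assay.

These functions chain the generator and the processing pipeline the way the
wet-lab experiments were run: a titration for calibration and dynamic range,
mismatch plates for specificity, expression plates for the cell-line panel,
and matched microarray/qPCR tables for cross-platform concordance.  They are
the computational core behind the ``demo`` subcommand and the analysis
drivers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import calibrate, quantify, relquant, simassay

__all__ = [
    "calibration_analysis",
    "specificity_analysis",
    "expression_analysis",
    "concordance_analysis",
    "run_demo",
]


def calibration_analysis(config: simassay.AssayConfig | None = None,
                         design: simassay.DilutionDesign | None = None,
                         n_replicates: int = 3):
    """Simulate a titration, fit the two-segment curve, detect the range."""
    config = config or simassay.AssayConfig()
    plate = simassay.simulate_calibration(config, design=design, n_replicates=n_replicates)
    curve = calibrate.curve_from_plate(plate, min_events=config.events_per_bead)
    fit = calibrate.fit_two_segment(curve)
    rng = calibrate.detect_linear_range(curve, fit)
    table = pd.DataFrame(
        [{
            "slope_low": fit.slope_low,
            "slope_high": fit.slope_high,
            "knot_fmol": fit.knot,
            "r2": fit.r2,
            "lod_fmol": rng.lower_fmol,
            "upper_fmol": rng.upper_fmol,
        }]
    )
    return plate, curve, fit, rng, table


def specificity_analysis(config: simassay.AssayConfig | None = None,
                         mirna: str = "miR-27a",
                         target_amount: float = 18.75,
                         n_replicates: int = 3) -> pd.DataFrame:
    """Simulate a mismatch plate and score 1MM/2MM signal as % of PM."""
    config = config or simassay.AssayConfig()
    plate = simassay.simulate_specificity(
        config, target_amount=target_amount, n_replicates=n_replicates, mirna=mirna
    )
    mfis = quantify.compute_mfi(plate.events, min_events=config.events_per_bead)
    corrected, _ = quantify.background_correct(mfis, plate.layout)
    normalized = quantify.spike_normalize(
        corrected, plate.truth["spike_region"], region_probe=plate.truth["region_probe"]
    )
    scores = quantify.specificity_score(
        normalized, pm_probe=mirna, mm_probes=[f"{mirna}-1MM", f"{mirna}-2MM"]
    )
    scores.insert(0, "mirna", mirna)
    return scores


def expression_analysis(config: simassay.AssayConfig | None = None,
                        panel: simassay.CellLinePanel | None = None,
                        n_wells: int = 3) -> pd.DataFrame:
    """Simulate an expression plate and summarize log2(sample/POOL)."""
    config = config or simassay.AssayConfig()
    panel = panel or simassay.default_panel()
    plate = simassay.simulate_expression(config, panel=panel, n_wells=n_wells)
    mfis = quantify.compute_mfi(plate.events, min_events=config.events_per_bead)
    corrected, _ = quantify.background_correct(mfis, plate.layout)
    normalized = quantify.spike_normalize(
        corrected, plate.truth["spike_region"], region_probe=plate.truth["region_probe"]
    )
    return quantify.summarize_expression(normalized, reference_sample=simassay.POOL)


def concordance_analysis(config: simassay.AssayConfig | None = None,
                         panel: simassay.CellLinePanel | None = None,
                         expression: pd.DataFrame | None = None):
    """Spearman concordance between bead, microarray and qPCR profiles.

    All platforms are put on a log2 scale before ranking (bead/array log2
    ratios; -ddCt for qPCR) — ranks are invariant to this, but the plotsized
    tables stay comparable.
    """
    config = config or simassay.AssayConfig()
    panel = panel or simassay.default_panel()
    if expression is None:
        expression = expression_analysis(config, panel)
    array, ct = simassay.simulate_matched_platforms(panel, config)
    rq = relquant.relative_quantification(ct, control_assay="RNU6B",
                                          calibrator_sample=simassay.POOL)

    bead_prof = expression.loc[expression["sample"] != simassay.POOL,
                               ["sample", "mirna", "log2_ratio"]].rename(
        columns={"log2_ratio": "value"})
    array_prof = array.rename(columns={"log2_ratio": "value"})
    qpcr = rq[rq["sample"] != simassay.POOL].copy()
    qpcr["value"] = -qpcr["delta_delta_ct"]  # log2 RQ
    qpcr_prof = qpcr.rename(columns={"assay": "mirna"})[["sample", "mirna", "value"]]

    profiles = {"xmap": bead_prof, "microarray": array_prof, "qpcr": qpcr_prof}
    concordance = relquant.spearman_concordance(profiles)
    return concordance, rq, profiles


def run_demo(seed: int = 1) -> dict[str, pd.DataFrame]:
    """The full synthetic workflow from one seed; returns named result tables."""
    config = simassay.AssayConfig(seed=int(seed))
    panel = simassay.default_panel()
    _, _, _, _, cal_table = calibration_analysis(config)
    spec = pd.concat(
        [specificity_analysis(config, mirna=m) for m in ("miR-27a", "miR-199a")],
        ignore_index=True,
    )
    expression = expression_analysis(config, panel)
    concordance, rq, _ = concordance_analysis(config, panel, expression)
    return {
        "calibration_fit": cal_table,
        "specificity": spec,
        "expression": expression,
        "rq": rq,
        "concordance": concordance,
    }
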