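#!/usr/bin/env python
"""Hybridization specificity of mismatch capture probes.

Runs the full MFI -> background -> spike-normalization -> %PM pipeline on
simulated specificity plates (18.75 fmol target, inside the linear range)
for miR-27a and miR-199a, in the simple single-target setting and against
the complex cell-line RNA background.  With the default configuration the
two-mismatch probes lose about 62% (miR-27a) and 85% (miR-199a) of the
perfect-match signal, each decrease Welch-significant at alpha = 0.05.
"""

import argparse
from pathlib import Path

import pandas as pd

from beadquant import beadio, quantify, simassay, workflow


def complex_specificity(cfg, mirna):
    plate = simassay.simulate_specificity(cfg, mirna=mirna, complex_background=True)
    mfis = quantify.compute_mfi(plate.events, min_events=cfg.events_per_bead)
    corrected, _ = quantify.background_correct(mfis, plate.layout)
    normalized = quantify.spike_normalize(
        corrected, plate.truth["spike_region"], region_probe=plate.truth["region_probe"]
    )
    scores = quantify.specificity_score(
        normalized, pm_probe=mirna, mm_probes=[f"{mirna}-1MM", f"{mirna}-2MM"]
    )
    scores.insert(0, "mirna", mirna)
    return scores


def main(seed: int = 1, out: Path = Path("results")) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg = simassay.AssayConfig(seed=seed)

    simple = pd.concat(
        [workflow.specificity_analysis(cfg, mirna=m) for m in ("miR-27a", "miR-199a")],
        ignore_index=True,
    )
    simple.insert(0, "setting", "single_target")
    complex_ = pd.concat(
        [complex_specificity(cfg, m) for m in ("miR-27a", "miR-199a")], ignore_index=True
    )
    complex_.insert(0, "setting", "complex_rna")
    table = pd.concat([simple, complex_], ignore_index=True)
    beadio.write_results(out / "specificity.tsv", table)
    print(table.to_string(index=False))
    two_mm = table[(table["setting"] == "single_target") & table["probe_id"].str.endswith("2MM")]
    for _, r in two_mm.iterrows():
        print(
            f"{r['mirna']}: two-mismatch drop {r['drop_pct']:.1f}% "
            f"(p = {r['p_value']:.2g}, n = {r['n']})"
        )


if __name__ == "__main__":
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--seed", type=int, default=1)
    p.add_argument("--out", type=Path, default=Path("results"))
    a = p.parse_args()
    main(a.seed, a.out)
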