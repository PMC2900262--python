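#!/usr/bin/env python
"""Relative miRNA expression across cell lines and platform concordance.

Quantifies the simulated 7-line panel against the pooled reference on the
bead platform (spike-normalized log2 ratios with propagated errors), runs
2^-ddCt on the matched TaqMan table, and compares the three platforms
(bead, microarray, qPCR) by per-miRNA Spearman correlation.  With default
noise the simulated platforms agree at rho ~ 0.9-1.0 and the two-group
pattern (miR-23a/miR-27a up in RH4/RH30) is recovered on all three.
"""

import argparse
from pathlib import Path

from beadquant import beadio, simassay, workflow


def main(seed: int = 1, out: Path = Path("results")) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg = simassay.AssayConfig(seed=seed)
    panel = simassay.default_panel()

    expression = workflow.expression_analysis(cfg, panel)
    concordance, rq, _ = workflow.concordance_analysis(cfg, panel, expression)
    beadio.write_results(out / "expression.tsv", expression)
    beadio.write_results(out / "rq.tsv", rq)
    beadio.write_results(out / "concordance.tsv", concordance)

    up = expression[
        expression["sample"].isin(simassay.FUSION_POS) & (expression["mirna"] == "miR-27a")
    ]
    print("miR-27a in fusion-positive lines (CI on the normalized-MFI scale):")
    print(
        up[["sample", "norm_mfi_mean", "ci95_low", "ci95_high", "log2_ratio", "log2_sd"]]
        .to_string(index=False)
    )
    print("\ncross-platform Spearman rho per miRNA:")
    print(concordance.to_string(index=False))


if __name__ == "__main__":
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--seed", type=int, default=1)
    p.add_argument("--out", type=Path, default=Path("results"))
    a = p.parse_args()
    main(a.seed, a.out)
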