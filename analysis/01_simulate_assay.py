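#!/usr/bin/env python
"""Generate the synthetic assay datasets every later step consumes.

Writes, under results/data/: the calibration titration (events, layout,
amounts; one run per stability day), a mismatch-specificity plate per
miRNA, the 7-cell-line + POOL expression plate, and the matched microarray
and TaqMan tables driven by the same latent abundances.
"""

import argparse
import json
from pathlib import Path

from beadquant import beadio, simassay

DAYS = (0, 20, 35, 50, 65, 80)


def main(seed: int = 1, out: Path = Path("results/data")) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg = simassay.AssayConfig(seed=seed)
    panel = simassay.default_panel()

    for day in DAYS:
        plate = simassay.simulate_calibration(cfg, days=(day,))
        stem = f"calibration_d{day}"
        beadio.write_bead_events(out / f"{stem}_events.csv", plate.events)
        beadio.write_plate_layout(out / f"{stem}_layout.tsv", plate.layout)
        (out / f"{stem}_truth.json").write_text(json.dumps(plate.truth, indent=2, default=str))

    for mirna in ("miR-27a", "miR-199a"):
        plate = simassay.simulate_specificity(cfg, mirna=mirna)
        stem = f"specificity_{mirna}"
        beadio.write_bead_events(out / f"{stem}_events.csv", plate.events)
        beadio.write_plate_layout(out / f"{stem}_layout.tsv", plate.layout)
        (out / f"{stem}_truth.json").write_text(json.dumps(plate.truth, indent=2, default=str))

    plate = simassay.simulate_expression(cfg, panel)
    beadio.write_bead_events(out / "expression_events.csv", plate.events)
    beadio.write_plate_layout(out / "expression_layout.tsv", plate.layout)
    (out / "expression_truth.json").write_text(json.dumps(plate.truth, indent=2, default=str))

    array, ct = simassay.simulate_matched_platforms(panel, cfg)
    beadio.write_results(out / "microarray_log2ratio.tsv", array)
    ct.to_csv(out / "taqman_ct.csv", index=False)

    n_events = sum(1 for _ in (out).glob("*_events.csv"))
    print(f"seed {seed}: wrote {n_events} bead-event tables plus platform tables to {out}")


if __name__ == "__main__":
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--seed", type=int, default=1)
    p.add_argument("--out", type=Path, default=Path("results/data"))
    a = p.parse_args()
    main(a.seed, a.out)
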