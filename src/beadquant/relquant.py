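"""TaqMan-style 2^-ddCt relative quantification and cross-platform concordance.

dCt = mean Ct(target) - mean Ct(endogenous control) per sample;
ddCt = dCt(sample) - dCt(calibrator); RQ = 2^-ddCt, so the calibrator's RQ
is 1 by construction and adding a constant number of cycles to every Ct of
one assay leaves all RQ values unchanged.

Cross-platform agreement is summarized per miRNA by the Spearman rank
correlation (average ranks for ties) over the samples shared by each pair
of platforms; ranks make the comparison invariant to the platforms'
different (monotone) scales.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["relative_quantification", "spearman_concordance"]


def relative_quantification(
    ct_table: pd.DataFrame, control_assay: str, calibrator_sample: str
) -> pd.DataFrame:
    """2^-ddCt relative quantification against an endogenous control.

    ``ct_table`` columns: sample, assay, replicate, ct.  Samples lacking the
    control assay are reported with missing values rather than dropped.
    """
    means = ct_table.groupby(["sample", "assay"])["ct"].mean().unstack("assay")
    if control_assay not in means.columns:
        raise ValueError(f"control assay {control_assay!r} absent from Ct table")
    if calibrator_sample not in means.index:
        raise ValueError(f"calibrator sample {calibrator_sample!r} absent from Ct table")
    if np.isnan(means.loc[calibrator_sample, control_assay]):
        raise ValueError(f"calibrator sample lacks the control assay {control_assay!r}")

    targets = [a for a in means.columns if a != control_assay]
    dct = means[targets].sub(means[control_assay], axis=0)
    rows = []
    for assay in targets:
        cal = dct.loc[calibrator_sample, assay]
        for sample in means.index:
            d = dct.loc[sample, assay]
            if np.isnan(d) or np.isnan(cal):
                rows.append((sample, assay, d, np.nan, np.nan))
            else:
                ddct = d - cal
                rows.append((sample, assay, d, ddct, 2.0 ** (-ddct)))
    return pd.DataFrame(rows, columns=["sample", "assay", "delta_ct", "delta_delta_ct", "rq"])


def spearman_concordance(profiles: dict[str, pd.DataFrame], min_shared: int = 4) -> pd.DataFrame:
    """Per-miRNA Spearman rho for every pair of platforms.

    ``profiles`` maps a platform name to a table with columns
    ``sample, mirna, value``.  Pairs sharing fewer than ``min_shared``
    samples for a miRNA are skipped with a warning.
    """
    tidy = {
        name: df.set_index(["sample", "mirna"])["value"] for name, df in profiles.items()
    }
    mirnas = sorted({m for s in tidy.values() for (_, m) in s.index})
    rows = []
    for a, b in itertools.combinations(sorted(tidy), 2):
        for m in mirnas:
            va = tidy[a].xs(m, level="mirna")
            vb = tidy[b].xs(m, level="mirna")
            shared = va.index.intersection(vb.index)
            if len(shared) < min_shared:
                warnings.warn(
                    f"{a} vs {b}, {m}: only {len(shared)} shared samples (< {min_shared}); skipped"
                )
                continue
            rho = stats.spearmanr(va.loc[shared], vb.loc[shared]).statistic
            rows.append((m, a, b, float(rho), len(shared)))
    return pd.DataFrame(rows, columns=["mirna", "platform_a", "platform_b", "rho", "n_samples"])
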