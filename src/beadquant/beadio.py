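"""Readers/writers for the pipeline's tabular artifacts and run configuration.

Single source of format truth:

* bead events — CSV, columns ``well,region,event,fluorescence`` (one row per
  bead event; ``event`` dense 1..n within each well/region);
* plate layouts — TSV, columns ``well,sample_id,role,replicate`` with role in
  {test, reference, background};
* probe tables — TSV mirroring the packaged capture-probe table;
* Ct tables — CSV, columns ``sample,assay,replicate,ct`` with Ct in (0, 45);
* results — TSV with fixed column order and 6-significant-digit numerics;
* run configuration — "key = value" sections (INI dialect) carrying every
  generative-model parameter plus the seed; unknown keys are errors.

Well coordinates are 96-well (A1-H12); multi-day simulated runs prefix the
day as ``d<day>.A1`` since each day is a separate physical plate.
"""

from __future__ import annotations

import configparser
import dataclasses
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .probekit import ProbeRecord

__all__ = [
    "WELL_PATTERN",
    "ROLES",
    "read_bead_events",
    "write_bead_events",
    "read_plate_layout",
    "write_plate_layout",
    "read_probe_table",
    "read_ct_table",
    "write_results",
    "read_config",
    "write_config",
]

WELL_PATTERN = re.compile(r"^(?:d\d+\.)?[A-H](?:[1-9]|1[0-2])$")
ROLES = ("test", "reference", "background")

EVENT_COLUMNS = ["well", "region", "event", "fluorescence"]
LAYOUT_COLUMNS = ["well", "sample_id", "role", "replicate"]
CT_COLUMNS = ["sample", "assay", "replicate", "ct"]


def _require_columns(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def _bad_line(df_index: int) -> int:
    # +2: header line plus 1-based counting.
    return int(df_index) + 2


def _check_wells(df: pd.DataFrame, path) -> None:
    bad = df.index[~df["well"].astype(str).str.match(WELL_PATTERN)]
    if len(bad):
        i = bad[0]
        raise ValueError(f"{path}: malformed well {df.loc[i, 'well']!r} at line {_bad_line(i)}")


def read_bead_events(path) -> pd.DataFrame:
    """Read and validate a bead-event CSV.

    Rejects negative fluorescence, malformed wells and duplicate
    (well, region, event) triples, naming the offending line.
    """
    df = pd.read_csv(path, dtype={"well": str})
    _require_columns(df, EVENT_COLUMNS, path)
    df = df[EVENT_COLUMNS].copy()
    _check_wells(df, path)
    df["region"] = df["region"].astype(int)
    df["event"] = df["event"].astype(int)
    df["fluorescence"] = df["fluorescence"].astype(float)
    neg = df.index[(df["fluorescence"] < 0) | ~np.isfinite(df["fluorescence"])]
    if len(neg):
        i = neg[0]
        raise ValueError(
            f"{path}: invalid fluorescence {df.loc[i, 'fluorescence']} at line {_bad_line(i)}"
        )
    dup = df.duplicated(subset=["well", "region", "event"])
    if dup.any():
        i = df.index[dup][0]
        raise ValueError(
            f"{path}: duplicate (well, region, event) "
            f"{tuple(df.loc[i, ['well', 'region', 'event']])} at line {_bad_line(i)}"
        )
    # event indices must be dense 1..n per (well, region)
    counts = df.groupby(["well", "region"])["event"].agg(["count", "min", "max"])
    sparse = counts[(counts["min"] != 1) | (counts["max"] != counts["count"])]
    if len(sparse):
        key = sparse.index[0]
        raise ValueError(f"{path}: event indices not dense 1..n for well/region {key}")
    return df


def write_bead_events(path, events: pd.DataFrame) -> None:
    events[EVENT_COLUMNS].to_csv(path, index=False)


def read_plate_layout(path) -> pd.DataFrame:
    """Read and validate a plate-layout TSV.

    A layout without background wells is accepted here; quantification steps
    that need a background model reject it at that point.
    """
    df = pd.read_csv(path, sep="\t", dtype={"well": str, "sample_id": str, "role": str})
    _require_columns(df, LAYOUT_COLUMNS, path)
    df = df[LAYOUT_COLUMNS].copy()
    _check_wells(df, path)
    bad_role = df.index[~df["role"].isin(ROLES)]
    if len(bad_role):
        i = bad_role[0]
        raise ValueError(
            f"{path}: unknown role {df.loc[i, 'role']!r} at line {_bad_line(i)} "
            f"(expected one of {ROLES})"
        )
    df["replicate"] = df["replicate"].astype(int)
    if (df["replicate"] < 1).any():
        i = df.index[df["replicate"] < 1][0]
        raise ValueError(f"{path}: replicate index < 1 at line {_bad_line(i)}")
    dup = df.duplicated(subset=["well"])
    if dup.any():
        i = df.index[dup][0]
        raise ValueError(f"{path}: duplicate well {df.loc[i, 'well']!r} at line {_bad_line(i)}")
    return df


def write_plate_layout(path, layout: pd.DataFrame) -> None:
    layout[LAYOUT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_probe_table(path) -> list[ProbeRecord]:
    """Read a capture-probe TSV into validated :class:`ProbeRecord` objects."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    _require_columns(
        df, ["id", "sequence", "length_nt", "parent_id", "mismatch_count", "bead_region"], path
    )
    records: list[ProbeRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        pid = row["id"]
        if pid in seen:
            raise ValueError(f"{path}: duplicate probe_id {pid!r} at line {_bad_line(i)}")
        seen.add(pid)
        region = row["bead_region"].strip()
        records.append(
            ProbeRecord(
                probe_id=pid,
                sequence=row["sequence"],
                length_nt=int(row["length_nt"]),
                target_mirna=row.get("target_mirna", ""),
                parent_id=row["parent_id"],
                mismatch_count=int(row["mismatch_count"]),
                bead_region=int(region) if region else None,
            )
        )
    return records


def read_ct_table(path) -> pd.DataFrame:
    """Read a qPCR Ct CSV; Ct values outside (0, 45) cycles are rejected."""
    df = pd.read_csv(path, dtype={"sample": str, "assay": str})
    _require_columns(df, CT_COLUMNS, path)
    df = df[CT_COLUMNS].copy()
    df["ct"] = df["ct"].astype(float)
    bad = df.index[(df["ct"] <= 0) | (df["ct"] >= 45)]
    if len(bad):
        i = bad[0]
        raise ValueError(f"{path}: Ct {df.loc[i, 'ct']} outside (0, 45) at line {_bad_line(i)}")
    return df


def write_results(path, table: pd.DataFrame) -> None:
    """Write a results TSV with fixed column order and %.6g numerics."""
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# run configuration


def write_config(path, config) -> None:
    """Write an AssayConfig as 'key = value' sections."""
    parser = configparser.ConfigParser()
    parser.optionxform = str  # keep case
    assay: dict[str, str] = {}
    for f in dataclasses.fields(config):
        value = getattr(config, f.name)
        if f.name in ("eff_1mm", "eff_2mm"):
            parser[f.name] = {k: repr(v) for k, v in value.items()}
        elif f.name == "bead_regions":
            assay[f.name] = ",".join(str(r) for r in value)
        else:
            assay[f.name] = repr(value) if not isinstance(value, str) else value
    parser["assay"] = assay
    with open(path, "w") as fh:
        parser.write(fh)


def read_config(path):
    """Read an AssayConfig; unknown sections or keys are errors (catch typos)."""
    from .simassay import AssayConfig

    parser = configparser.ConfigParser()
    parser.optionxform = str
    read = parser.read(path)
    if not read:
        raise FileNotFoundError(path)
    known_sections = {"assay", "eff_1mm", "eff_2mm"}
    unknown = set(parser.sections()) - known_sections
    if unknown:
        raise ValueError(f"{path}: unknown config section(s) {sorted(unknown)}")
    field_types = {f.name: f for f in dataclasses.fields(AssayConfig)}
    kwargs: dict = {}
    for key, raw in parser["assay"].items():
        if key not in field_types or key in ("eff_1mm", "eff_2mm"):
            raise ValueError(f"{path}: unknown config key {key!r} in [assay]")
        if key == "bead_regions":
            kwargs[key] = tuple(int(x) for x in raw.split(","))
        elif key in ("seed", "events_per_bead", "stable_days", "n_background", "calibration_region"):
            kwargs[key] = int(raw)
        elif key == "signal_mode":
            kwargs[key] = raw
        else:
            kwargs[key] = float(raw)
    for section in ("eff_1mm", "eff_2mm"):
        if parser.has_section(section):
            kwargs[section] = {k: float(v) for k, v in parser[section].items()}
    return AssayConfig(**kwargs)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
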