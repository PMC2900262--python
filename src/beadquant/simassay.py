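"""Synthetic bead-assay generator.

Emulates a suspension bead array read on a flow analyzer: each well contains
a mixture of colour-coded microsphere sets ("regions"), each coupled to one
capture probe; the instrument records the reporter fluorescence of
``events_per_bead`` beads per region per well, and downstream analysis
summarizes each (well, region) by the median fluorescence intensity (MFI).

Generative model
----------------
The probe-bound signal follows, on the log10-log10 scale, two connected
straight lines: slope ``s1`` (default 0.94) below a saturation knot and
``s2`` (default 0.15) above it, anchored at ``(knot_fmol, mfi_at_knot)``.
An alternative Langmuir-isotherm mode (``bmax*C/(kd+C)``) is provided; its
log-log slope tends to 1 as C -> 0, so the two modes agree in the dilute
limit.  Per-event scatter is lognormal and median-parameterized, so the
per-region median is an unbiased estimator of the model signal.  Probe-bead
conjugates are stable for ``stable_days`` days; afterwards the signal decays
as exp(-aging_lambda * (day - stable_days)).

Background fluorescence has median ``bg_median``; its well-to-well
variability (``bg_well_sd``) is expressed in the dedicated no-target wells
from which the background model is estimated, while in target wells the
background contributes its median value on top of the probe signal.

Mismatch capture probes bind at a configured fraction of the perfect-match
signal (``eff_1mm``/``eff_2mm``).  Sample labeling efficiency is a per-sample
lognormal factor that scales miRNA and spike-in signal alike — which is
exactly what spike normalization exploits to cancel it.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AssayConfig",
    "DilutionDesign",
    "CellLinePanel",
    "SimulatedPlate",
    "default_panel",
    "make_dilution_series",
    "signal_median",
    "retention",
    "simulate_calibration",
    "simulate_specificity",
    "simulate_expression",
    "simulate_matched_platforms",
]

FUSION_POS = ("RH4", "RH30")
CELL_LINES = ("RD", "CCA", "SMS-CTR", "RH36", "RH18", "RH4", "RH30")
MIRNAS = ("miR-23a", "miR-27a", "miR-199a")
SPIKE = "Spike 18"
POOL = "POOL"


@dataclass
class AssayConfig:
    """Full generative model for the simulated assay.

    The 2-mismatch efficiencies (0.38, 0.15) encode the observed fractional
    signal after the printed 62%/85% drops; the 1-mismatch values are
    plausible placeholders satisfying PM > 1MM > 2MM (no number is printed
    for them).
    """

    seed: int = 0
    events_per_bead: int = 100
    signal_mode: str = "piecewise"  # or "langmuir"
    s1: float = 0.94
    s2: float = 0.15
    knot_fmol: float = 18.75
    mfi_at_knot: float = 3000.0
    langmuir_bmax: float = 25000.0
    langmuir_kd: float = 75.0
    event_cv: float = 0.25
    bg_median: float = 30.0
    bg_well_sd: float = 4.0
    eff_1mm: dict = field(default_factory=lambda: {"miR-27a": 0.70, "miR-199a": 0.55})
    eff_2mm: dict = field(default_factory=lambda: {"miR-27a": 0.38, "miR-199a": 0.15})
    aging_lambda: float = 0.004  # per day, after stable_days
    stable_days: int = 35
    labeling_eff_sd: float = 0.3  # lognormal sigma of per-sample labeling factor
    bead_regions: tuple = (1, 21, 51, 57)
    n_background: int = 16  # no-target wells per plate
    calibration_region: int = 51  # miR-199a beads, as in the titration experiment
    spike_fmol: float = 4.6875  # spike-in amount for specificity plates
    expr_gain: float = 150.0  # MFI per latent abundance unit on expression plates
    spike_level: float = 10.0  # spike-in latent level on expression plates

    def validate(self) -> None:
        if self.events_per_bead < 1:
            raise ValueError("events_per_bead must be >= 1")
        if self.event_cv < 0 or self.bg_well_sd < 0 or self.labeling_eff_sd < 0:
            raise ValueError("cv and sd parameters must be >= 0")
        if self.signal_mode not in ("piecewise", "langmuir"):
            raise ValueError(f"unknown signal_mode {self.signal_mode!r}")
        for name, eff in (("eff_1mm", self.eff_1mm), ("eff_2mm", self.eff_2mm)):
            for k, v in eff.items():
                if not 0 < v <= 1:
                    raise ValueError(f"{name}[{k!r}]={v} outside (0, 1]")
        for k in self.eff_2mm:
            if k in self.eff_1mm and not self.eff_2mm[k] < self.eff_1mm[k] < 1:
                raise ValueError(f"require eff_2mm < eff_1mm < 1 for probe {k!r}")
        if len(self.bead_regions) != len(set(self.bead_regions)):
            raise ValueError("bead_regions must be distinct")

    def replace(self, **kwargs) -> "AssayConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class DilutionDesign:
    """Geometric dilution series: start, start/fold, ... (n_points values)."""

    start_fmol: float = 300.0
    fold: float = 4.0
    n_points: int = 8


@dataclass
class CellLinePanel:
    """Seven cell lines plus a pooled reference with latent miRNA abundances.

    ``latent_abundance`` maps (sample, miRNA) to relative units; the POOL is
    constrained to the arithmetic mean of the seven samples per miRNA.
    """

    sample_ids: tuple
    latent_abundance: dict
    group: dict

    def __post_init__(self) -> None:
        samples = [s for s in self.sample_ids if s != POOL]
        if POOL not in self.sample_ids:
            raise ValueError("panel must include the POOL reference")
        mirnas = sorted({m for (s, m) in self.latent_abundance if s != POOL})
        for m in mirnas:
            mean = np.mean([self.latent_abundance[(s, m)] for s in samples])
            pool = self.latent_abundance.get((POOL, m))
            if pool is None:
                self.latent_abundance[(POOL, m)] = float(mean)
            elif not math.isclose(pool, mean, rel_tol=1e-9):
                raise ValueError(f"POOL abundance for {m} must equal the mean of the samples")

    @property
    def mirnas(self) -> list[str]:
        return sorted({m for (_, m) in self.latent_abundance})


def default_panel() -> CellLinePanel:
    """Synthetic two-group panel: miR-23a/miR-27a up, miR-199a down in the
    fusion-positive lines (RH4, RH30).  All numbers are invented fixed values."""
    neg = ("RD", "CCA", "SMS-CTR", "RH36", "RH18")
    base = {
        "miR-23a": dict(zip(neg, (1.0, 1.3, 0.8, 1.1, 0.9)), RH4=4.5, RH30=5.5),
        "miR-27a": dict(zip(neg, (1.2, 0.9, 1.0, 1.4, 1.1)), RH4=6.0, RH30=7.0),
        "miR-199a": dict(zip(neg, (3.0, 2.4, 2.8, 3.5, 2.6)), RH4=0.8, RH30=0.6),
    }
    latent = {(s, m): float(v) for m, by_sample in base.items() for s, v in by_sample.items()}
    group = {s: ("fusion_pos" if s in FUSION_POS else "fusion_neg") for s in CELL_LINES}
    return CellLinePanel(
        sample_ids=CELL_LINES + (POOL,),
        latent_abundance=latent,
        group=group,
    )


@dataclass
class SimulatedPlate:
    """Bead events + plate layout + generative truth for one simulated run."""

    events: pd.DataFrame  # well, region, event, fluorescence
    layout: pd.DataFrame  # well, sample_id, role, replicate
    truth: dict


# ---------------------------------------------------------------------------
# model primitives


def make_dilution_series(design: DilutionDesign | None = None) -> list[float]:
    """Amounts (fmol) of the geometric dilution series, descending."""
    design = design or DilutionDesign()
    if design.fold <= 1:
        raise ValueError("dilution fold must be > 1")
    if design.start_fmol <= 0 or design.n_points < 1:
        raise ValueError("need start_fmol > 0 and n_points >= 1")
    return [design.start_fmol / design.fold**i for i in range(design.n_points)]


def signal_median(config: AssayConfig, amount_fmol: float) -> float:
    """Median probe-bound signal (background excluded) at a target amount."""
    if amount_fmol <= 0:
        return 0.0
    if config.signal_mode == "piecewise":
        s = config.s1 if amount_fmol <= config.knot_fmol else config.s2
        return config.mfi_at_knot * (amount_fmol / config.knot_fmol) ** s
    return config.langmuir_bmax * amount_fmol / (config.langmuir_kd + amount_fmol)


def retention(config: AssayConfig, day: float) -> float:
    """Probe-bead conjugate signal retention at `day` days post-conjugation."""
    if day < 0:
        raise ValueError("day must be >= 0")
    if day <= config.stable_days:
        return 1.0
    return math.exp(-config.aging_lambda * (day - config.stable_days))


def _well_names(n: int, prefix: str = "") -> list[str]:
    if n > 96:
        raise ValueError(f"{n} wells exceed one 96-well plate")
    names = [f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13)]
    return [prefix + w for w in names[:n]]


def _draw_events(rng: np.random.Generator, median: float, n: int, cv: float) -> np.ndarray:
    """Lognormal event fluorescence with the given median and fractional CV."""
    median = max(median, 1e-9)
    if cv <= 0:
        return np.full(n, median)
    sigma = math.sqrt(math.log1p(cv * cv))
    return median * np.exp(sigma * rng.standard_normal(n))


def _emit(rows: list, rng, config: AssayConfig, well: str, region: int, median: float) -> None:
    fl = _draw_events(rng, median, config.events_per_bead, config.event_cv)
    rows.append(
        pd.DataFrame(
            {
                "well": well,
                "region": region,
                "event": np.arange(1, config.events_per_bead + 1),
                "fluorescence": fl,
            }
        )
    )


def _background_median(rng: np.random.Generator, config: AssayConfig) -> float:
    return max(rng.normal(config.bg_median, config.bg_well_sd), 1e-6)


def _assemble(rows, layout_rows, truth) -> SimulatedPlate:
    events = pd.concat(rows, ignore_index=True)
    layout = pd.DataFrame(layout_rows, columns=["well", "sample_id", "role", "replicate"])
    return SimulatedPlate(events=events, layout=layout, truth=truth)


# ---------------------------------------------------------------------------
# experiment simulators


def simulate_calibration(
    config: AssayConfig | None = None,
    design: DilutionDesign | None = None,
    n_replicates: int = 3,
    days=(0,),
) -> SimulatedPlate:
    """Titration of a biotinylated target against its capture-probe beads.

    One 96-well run per requested day: ``n_points`` amounts x ``n_replicates``
    target wells plus ``n_background`` no-target wells.  All configured bead
    regions are present in every well; only ``calibration_region`` carries
    target-driven signal.  When several days are simulated in one call, well
    IDs are prefixed ``d<day>.`` (separate physical plates).
    """
    config = config or AssayConfig()
    config.validate()
    design = design or DilutionDesign()
    if any(d < 0 for d in days):
        raise ValueError("days must be >= 0")
    amounts = make_dilution_series(design)
    rng = np.random.default_rng(config.seed)

    rows: list = []
    layout_rows: list = []
    amounts_map: dict[str, float] = {}
    well_day: dict[str, int] = {}
    multi = len(days) > 1
    for day in days:
        prefix = f"d{day}." if multi else ""
        wells = iter(_well_names(len(amounts) * n_replicates + config.n_background, prefix))
        for amount in amounts:
            sample_id = f"cal-{amount:.10g}fmol" + (f"-d{day}" if multi else "")
            amounts_map[sample_id] = amount
            signal = signal_median(config, amount) * retention(config, day)
            for rep in range(1, n_replicates + 1):
                well = next(wells)
                layout_rows.append((well, sample_id, "test", rep))
                well_day[well] = day
                for region in config.bead_regions:
                    median = signal + config.bg_median if region == config.calibration_region else config.bg_median
                    _emit(rows, rng, config, well, region, median)
        for rep in range(1, config.n_background + 1):
            well = next(wells)
            layout_rows.append((well, "BACKGROUND", "background", rep))
            well_day[well] = day
            for region in config.bead_regions:
                _emit(rows, rng, config, well, region, _background_median(rng, config))

    truth = {
        "kind": "calibration",
        "config": dataclasses.asdict(config),
        "amounts": amounts_map,
        "well_day": well_day,
        "region": config.calibration_region,
        "days": list(days),
    }
    return _assemble(rows, layout_rows, truth)


def simulate_specificity(
    config: AssayConfig | None = None,
    target_amount: float = 18.75,
    n_replicates: int = 3,
    complex_background: bool = False,
    mirna: str = "miR-27a",
    panel: CellLinePanel | None = None,
) -> SimulatedPlate:
    """Hybridization of one target against PM / 1MM / 2MM probes plus spike.

    Simple mode: ``n_replicates`` wells at ``target_amount`` fmol.  Complex
    mode: the panel's 7 samples + POOL, each with a latent-scaled target
    amount and a per-sample labeling factor that multiplies miRNA and spike
    signal alike.
    """
    config = config or AssayConfig()
    config.validate()
    if target_amount <= 0:
        raise ValueError("target_amount must be > 0")
    if mirna not in config.eff_1mm or mirna not in config.eff_2mm:
        raise ValueError(f"no configured mismatch efficiencies for probe {mirna!r}")
    regions = sorted(config.bead_regions)
    if len(regions) < 4:
        raise ValueError("need at least 4 bead regions (PM, 1MM, 2MM, spike)")
    region_probe = {
        regions[0]: mirna,
        regions[1]: f"{mirna}-1MM",
        regions[2]: f"{mirna}-2MM",
        regions[3]: SPIKE,
    }
    eff = {mirna: 1.0, f"{mirna}-1MM": config.eff_1mm[mirna], f"{mirna}-2MM": config.eff_2mm[mirna]}
    rng = np.random.default_rng(config.seed)

    if complex_background:
        panel = panel or default_panel()
        pool_latent = panel.latent_abundance[(POOL, mirna)]
        samples = list(panel.sample_ids)
        latents = {s: panel.latent_abundance[(s, mirna)] / pool_latent for s in samples}
    else:
        samples = ["TARGET"]
        latents = {"TARGET": 1.0}
    factors = {
        s: (math.exp(rng.normal(0.0, config.labeling_eff_sd)) if complex_background else 1.0)
        for s in samples
    }

    spike_signal = signal_median(config, config.spike_fmol)
    rows: list = []
    layout_rows: list = []
    wells = iter(_well_names(len(samples) * n_replicates + config.n_background))
    for s in samples:
        f = factors[s]
        pm_signal = signal_median(config, target_amount * latents[s])
        role = "reference" if s == POOL else "test"
        for rep in range(1, n_replicates + 1):
            well = next(wells)
            layout_rows.append((well, s, role, rep))
            for region in regions[:3]:
                median = f * eff[region_probe[region]] * pm_signal + config.bg_median
                _emit(rows, rng, config, well, region, median)
            _emit(rows, rng, config, well, regions[3], f * spike_signal + config.bg_median)
    for rep in range(1, config.n_background + 1):
        well = next(wells)
        layout_rows.append((well, "BACKGROUND", "background", rep))
        for region in regions:
            _emit(rows, rng, config, well, region, _background_median(rng, config))

    truth = {
        "kind": "specificity",
        "config": dataclasses.asdict(config),
        "mirna": mirna,
        "target_amount": target_amount,
        "region_probe": region_probe,
        "efficiencies": eff,
        "labeling_factors": factors,
        "latents": latents,
        "spike_region": regions[3],
    }
    return _assemble(rows, layout_rows, truth)


def simulate_expression(
    config: AssayConfig | None = None,
    panel: CellLinePanel | None = None,
    n_wells: int = 3,
    labeling_factors: dict | None = None,
) -> SimulatedPlate:
    """Expression plate: 7 samples + POOL x ``n_wells`` wells, 4 regions each
    (three miRNA probes + spike), plus background wells.

    Signals use a linear response (MFI = gain * latent * labeling_factor +
    background): the assay is operated inside its linear dynamic range.
    ``labeling_factors`` overrides the per-sample lognormal draw (useful to
    demonstrate that spike normalization cancels it).
    """
    config = config or AssayConfig()
    config.validate()
    panel = panel or default_panel()
    if n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    mirnas = [m for m in panel.mirnas]
    regions = sorted(config.bead_regions)
    if len(mirnas) + 1 > len(regions):
        raise ValueError(
            f"{len(mirnas)} probes + spike exceed the {len(regions)} configured bead regions"
        )
    region_probe = dict(zip(regions, mirnas + [SPIKE]))
    rng = np.random.default_rng(config.seed)
    samples = list(panel.sample_ids)
    if labeling_factors is None:
        factors = {s: math.exp(rng.normal(0.0, config.labeling_eff_sd)) for s in samples}
    else:
        factors = {s: float(labeling_factors.get(s, 1.0)) for s in samples}

    rows: list = []
    layout_rows: list = []
    wells = iter(_well_names(len(samples) * n_wells + config.n_background))
    for s in samples:
        f = factors[s]
        role = "reference" if s == POOL else "test"
        for rep in range(1, n_wells + 1):
            well = next(wells)
            layout_rows.append((well, s, role, rep))
            for region, probe in region_probe.items():
                latent = config.spike_level if probe == SPIKE else panel.latent_abundance[(s, probe)]
                median = config.expr_gain * latent * f + config.bg_median
                _emit(rows, rng, config, well, region, median)
    for rep in range(1, config.n_background + 1):
        well = next(wells)
        layout_rows.append((well, "BACKGROUND", "background", rep))
        for region in regions:
            _emit(rows, rng, config, well, region, _background_median(rng, config))

    truth = {
        "kind": "expression",
        "config": dataclasses.asdict(config),
        "region_probe": region_probe,
        "spike_region": regions[len(mirnas)],
        "labeling_factors": factors,
        "latent_abundance": {f"{s}|{m}": v for (s, m), v in panel.latent_abundance.items()},
        "samples": samples,
    }
    return _assemble(rows, layout_rows, truth)


def simulate_matched_platforms(
    panel: CellLinePanel | None = None,
    config: AssayConfig | None = None,
    array_sd: float = 0.25,
    ct_sd: float = 0.15,
    ct_intercept: float = 30.0,
    rnu6b_ct: float = 20.0,
    n_ct_replicates: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Matched microarray log2-ratios and TaqMan Ct values from the panel's
    latent abundances.

    Microarray: log2(sample/POOL) = latent log-ratio + N(0, array_sd).
    qPCR: Ct = ct_intercept - log2(latent) + N(0, ct_sd), in
    ``n_ct_replicates`` technical replicates, plus constant-abundance RNU6B
    rows serving as the endogenous control.
    """
    panel = panel or default_panel()
    config = config or AssayConfig()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    samples = [s for s in panel.sample_ids if s != POOL]
    mirnas = panel.mirnas

    array_rows = []
    for s in samples:
        for m in mirnas:
            ratio = panel.latent_abundance[(s, m)] / panel.latent_abundance[(POOL, m)]
            array_rows.append((s, m, math.log2(ratio) + rng.normal(0.0, array_sd)))
    array = pd.DataFrame(array_rows, columns=["sample", "mirna", "log2_ratio"])

    ct_rows = []
    for s in samples + [POOL]:
        for m in mirnas:
            base = ct_intercept - math.log2(panel.latent_abundance[(s, m)])
            for rep in range(1, n_ct_replicates + 1):
                ct_rows.append((s, m, rep, base + rng.normal(0.0, ct_sd)))
        for rep in range(1, n_ct_replicates + 1):
            ct_rows.append((s, "RNU6B", rep, rnu6b_ct + rng.normal(0.0, ct_sd)))
    ct = pd.DataFrame(ct_rows, columns=["sample", "assay", "replicate", "ct"])
    return array, ct
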