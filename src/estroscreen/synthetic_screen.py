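"""Synthetic screen generator.

Emulates the statistical structure of a paired vehicle/estrogen 384-well
growth-inhibition screen on immortalized endometrial stromal cell lines, so
every downstream stage (normalization, QC gating, %E-DI hit calling, 4PL
confirmation fitting) is testable without raw screen data.

The generative model, per well:

    count = round(baseline * growth(condition) * effect(compound, line, condition)
                  * LogNormal(1, cv))

where ``growth`` is 1 under vehicle and ``estrogen_growth_factor`` under
estrogen, and ``effect`` is the compound's programmed survival fraction.
Library compounds fall into three independent strata: a small fraction is
vehicle-toxic (survival < 0.5 without estrogen), a rare tail are strong
estrogen-specific inhibitors ("true hits"), and the remainder carry mild
background estrogen-driven inhibition drawn from a normal distribution.
The multiplicative lognormal noise is mean-1 with coefficient of variation
``well_noise_cv`` (sigma = sqrt(ln(1 + cv^2))); cell counts are positive
with variance growing with the mean, which a lognormal reproduces and an
additive Gaussian would not.

Every dataset is emitted together with a truth ledger (DataFrame of the
programmed per-compound effects) so each pipeline stage can be checked for
parameter recovery. One RNG stream is derived per plate from
(seed, plate index, cell-line index, condition index), so any plate can be
regenerated independently and the whole dataset is reproducible from the
seed alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .plate_model import (
    CONDITIONS,
    ROWS,
    PlateLayout,
    RawPlate,
    ScreenDataset,
    WellAddress,
    WellEntry,
    WellRole,
)

#: Library compound concentration in the primary screen (µM).
LIBRARY_DOSE_UM = 10.0

#: QC titration: 10 doses, 1:2 serial dilution from 50 µM (terminal dose
#: 50/2^9 ≈ 0.098 µM; sometimes quoted rounded as 0.05 µM).
QC_TITRATION_DOSES_UM = tuple(50.0 / 2**k for k in range(10))

#: Confirmation screen: 5 doses, 1:5 serial dilution from 10 µM (terminal
#: dose 10/5^4 = 0.016 µM; sometimes quoted rounded as 0.02 µM).
CONFIRMATION_DOSES_UM = tuple(10.0 / 5**k for k in range(5))


class GeneratorConfigError(ValueError):
    """Invalid synthetic-screen configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters of the synthetic primary screen.

    Defaults mirror the screen design this pipeline targets: 352 library
    wells per plate at 10 µM, two cell lines, ~1.6-fold estrogen growth
    stimulation, 8% multiplicative well noise, 8% vehicle-toxic compounds,
    and a 1.5% tail of strong estrogen-specific inhibitors whose %E-DI is
    uniform on 75-98 against a background %E-DI of N(5, 12).
    """

    n_library_plates: int = 10
    compounds_per_plate: int = 352
    cell_lines: tuple[str, ...] = ("1455", "1458")
    baseline_count: float = 1000.0
    estrogen_growth_factor: float = 1.6
    well_noise_cv: float = 0.08
    toxic_fraction: float = 0.08
    hit_fraction: float = 0.015
    background_inhibition_mean: float = 5.0
    background_inhibition_sd: float = 12.0
    hit_inhibition_range: tuple[float, float] = (75.0, 98.0)
    #: Residual survival fraction of QC-positive wells (both conditions).
    qc_positive_residual: float = 0.05
    qc_positive_compounds: tuple[str, ...] = ("panobinostat", "salinomycin")
    qc_negative_compounds: tuple[str, ...] = ("fulvestrant",)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.compounds_per_plate <= 352:
            raise GeneratorConfigError(
                f"compounds_per_plate must be in 1..352, got {self.compounds_per_plate}"
            )
        if self.n_library_plates < 1:
            raise GeneratorConfigError("need at least one library plate")
        for name in ("toxic_fraction", "hit_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GeneratorConfigError(f"{name} must be in [0, 1], got {v}")
        if self.estrogen_growth_factor <= 0:
            raise GeneratorConfigError("estrogen_growth_factor must be positive")
        if self.well_noise_cv < 0:
            raise GeneratorConfigError("well_noise_cv must be non-negative")
        lo, hi = self.hit_inhibition_range
        if not lo <= hi:
            raise GeneratorConfigError("hit_inhibition_range must be (low, high)")


@dataclass(frozen=True)
class DoseResponseTruth:
    """Programmed 4PL truth for one compound on one cell line.

    ``top``/``bottom`` are % survival asymptotes at zero/saturating dose,
    ``log10_ic50`` is in log10 µM, and ``hill`` > 0 means survival falls as
    dose rises.
    """

    compound_id: str
    cell_line_id: str
    top: float = 100.0
    bottom: float = 0.0
    log10_ic50: float = 0.0
    hill: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.bottom <= self.top:
            raise GeneratorConfigError(
                f"{self.compound_id}: need 0 <= bottom <= top, got "
                f"({self.bottom}, {self.top})"
            )

    @property
    def ic50_uM(self) -> float:
        return 10.0 ** self.log10_ic50

    def survival_at(self, dose_uM: float) -> float:
        ratio = (dose_uM / self.ic50_uM) ** self.hill
        return self.bottom + (self.top - self.bottom) / (1.0 + ratio)


# ---------------------------------------------------------------------------
# RNG plumbing
# ---------------------------------------------------------------------------

_TRUTH_STREAM = 0
_PLATE_STREAM = 1
_QC_STREAM = 2
_CONFIRM_STREAM = 3


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _sigma_from_cv(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def _noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative lognormal factors with the given CV."""
    if cv == 0.0:
        return np.ones(size)
    sigma = _sigma_from_cv(cv)
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# Layout construction
# ---------------------------------------------------------------------------


def build_library_layout(
    plate_id: str,
    compound_ids: list[str],
    config: GeneratorConfig,
    dose_uM: float = LIBRARY_DOSE_UM,
) -> PlateLayout:
    """Canonical library-plate layout.

    Compounds fill columns 1-22 row-major; column 23 holds 8 DMSO wells
    (rows A-H) and 4 media wells (rows I-L); QC compounds occupy 4-well
    blocks from column 23 row M onward into column 24.
    """
    if len(compound_ids) > 352:
        raise GeneratorConfigError(f"{len(compound_ids)} compounds exceed 352 library wells")
    wells: dict[WellAddress, WellEntry] = {}
    library_slots = [WellAddress(r, c) for r in ROWS for c in range(1, 23)]
    for addr, cid in zip(library_slots, compound_ids):
        wells[addr] = WellEntry(WellRole.LIBRARY, cid, dose_uM)
    for row in ROWS[:8]:
        wells[WellAddress(row, 23)] = WellEntry(WellRole.VEHICLE, None, None)
    for row in ROWS[8:12]:
        wells[WellAddress(row, 23)] = WellEntry(WellRole.MEDIA, None, None)
    qc_slots = [WellAddress(r, 23) for r in ROWS[12:]] + [
        WellAddress(r, 24) for r in ROWS
    ]
    qc_roles = [(cid, WellRole.QC_POSITIVE) for cid in config.qc_positive_compounds] + [
        (cid, WellRole.QC_NEGATIVE) for cid in config.qc_negative_compounds
    ]
    needed = 4 * len(qc_roles)
    if needed > len(qc_slots):
        raise GeneratorConfigError("too many QC compounds for columns 23-24")
    i = 0
    for cid, role in qc_roles:
        for _ in range(4):
            wells[qc_slots[i]] = WellEntry(role, cid, 50.0)
            i += 1
    return PlateLayout(plate_id=plate_id, wells=wells)


# ---------------------------------------------------------------------------
# Truth ledger
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = [
    "compound_id",
    "cell_line",
    "is_toxic",
    "is_hit",
    "true_vehicle_effect",
    "true_estrogen_effect",
    "true_edi",
]


def _draw_truth(config: GeneratorConfig, compound_ids: list[str]) -> pd.DataFrame:
    """Programmed per-(compound, cell line) survival effects.

    Toxicity is a per-compound property (vehicle survival drawn per line in
    0.05-0.45); hit status is drawn independently per (compound, line), and
    the estrogen-condition effect is derived from the programmed %E-DI via
    effect_estrogen = effect_vehicle * (1 - edi/100).
    """
    rng = _rng(config.seed, _TRUTH_STREAM)
    n = len(compound_ids)
    is_toxic = rng.random(n) < config.toxic_fraction
    rows = []
    for line in config.cell_lines:
        is_hit = rng.random(n) < config.hit_fraction
        veh = np.ones(n)
        veh[is_toxic] = rng.uniform(0.05, 0.45, size=int(is_toxic.sum()))
        if config.background_inhibition_sd > 0:
            edi = rng.normal(
                config.background_inhibition_mean, config.background_inhibition_sd, n
            )
        else:
            edi = np.full(n, config.background_inhibition_mean)
        lo, hi = config.hit_inhibition_range
        edi[is_hit] = rng.uniform(lo, hi, size=int(is_hit.sum()))
        edi = np.minimum(edi, 100.0)  # survival cannot go negative
        est = veh * (1.0 - edi / 100.0)
        rows.append(
            pd.DataFrame(
                {
                    "compound_id": compound_ids,
                    "cell_line": line,
                    "is_toxic": is_toxic,
                    "is_hit": is_hit,
                    "true_vehicle_effect": veh,
                    "true_estrogen_effect": est,
                    "true_edi": edi,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)[TRUTH_COLUMNS]


def write_truth_ledger(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Primary screen
# ---------------------------------------------------------------------------


def _well_effect(
    entry: WellEntry,
    condition: str,
    effects: dict[tuple[str, str], tuple[float, float]],
    line: str,
    config: GeneratorConfig,
) -> float:
    if entry.role is WellRole.LIBRARY:
        veh, est = effects[(entry.compound_id, line)]
        return veh if condition == "vehicle" else est
    if entry.role is WellRole.QC_POSITIVE:
        return config.qc_positive_residual
    # DMSO vehicle, media, and QC-negative wells all grow unimpeded.
    return 1.0


def simulate_primary_screen(config: GeneratorConfig) -> ScreenDataset:
    """Generate a paired vehicle/estrogen primary screen.

    Returns a :class:`ScreenDataset` whose ``truth`` attribute holds the
    programmed effect ledger. Fully reproducible from ``config.seed``.
    """
    n_compounds = config.n_library_plates * config.compounds_per_plate
    compound_ids = [f"CPD{i + 1:05d}" for i in range(n_compounds)]
    truth = _draw_truth(config, compound_ids)
    effects = {
        (r.compound_id, r.cell_line): (r.true_vehicle_effect, r.true_estrogen_effect)
        for r in truth.itertuples(index=False)
    }

    layouts: dict[str, PlateLayout] = {}
    plates: list[RawPlate] = []
    pairing: dict[tuple[str, str], tuple[RawPlate, RawPlate]] = {}
    for p in range(config.n_library_plates):
        layout_id = f"LP{p + 1:03d}"
        ids = compound_ids[p * config.compounds_per_plate : (p + 1) * config.compounds_per_plate]
        layout = build_library_layout(layout_id, ids, config)
        layouts[layout_id] = layout
        addrs = layout.non_empty_wells()
        for li, line in enumerate(config.cell_lines):
            pair = []
            for ci, condition in enumerate(CONDITIONS):
                rng = _rng(config.seed, _PLATE_STREAM, p, li, ci)
                growth = config.estrogen_growth_factor if condition == "estrogen" else 1.0
                noise = _noise(rng, config.well_noise_cv, len(addrs))
                counts = {}
                for addr, factor in zip(addrs, noise):
                    eff = _well_effect(layout.wells[addr], condition, effects, line, config)
                    counts[addr] = int(round(config.baseline_count * growth * eff * factor))
                plate = RawPlate(
                    plate_id=f"{layout_id}-{line}-{condition}",
                    cell_line_id=line,
                    condition=condition,
                    counts=counts,
                )
                plates.append(plate)
                pair.append(plate)
            pairing[(layout_id, line)] = (pair[0], pair[1])
    return ScreenDataset(layouts=layouts, plates=plates, pairing=pairing, truth=truth)


# ---------------------------------------------------------------------------
# QC titration and confirmation screens
# ---------------------------------------------------------------------------


def simulate_qc_titration(
    config: GeneratorConfig,
    qc_profiles: dict[str, dict[str, DoseResponseTruth]],
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Triplicate 10-dose (1:2 from 50 µM) titration per QC compound.

    ``qc_profiles`` maps compound id -> condition -> 4PL truth. Returns a
    tidy table (compound_id, condition, dose_uM, replicate, response_pct);
    responses are % survival from the 4PL times multiplicative noise.
    """
    rng = _rng(config.seed, _QC_STREAM)
    rows = []
    for cid, by_condition in qc_profiles.items():
        for condition, truth in by_condition.items():
            for dose in QC_TITRATION_DOSES_UM:
                clean = truth.survival_at(dose)
                factors = _noise(rng, config.well_noise_cv, n_replicates)
                for rep, f in enumerate(factors, start=1):
                    rows.append((cid, condition, dose, rep, clean * f))
    return pd.DataFrame(
        rows, columns=["compound_id", "condition", "dose_uM", "replicate", "response_pct"]
    )


def simulate_confirmation_screen(
    truths: list[DoseResponseTruth],
    config: GeneratorConfig,
) -> pd.DataFrame:
    """Two confirmation screens over the 5-dose 1:5 series from 10 µM.

    Screen 1 is run in singlet, screen 2 in duplicate. Returns a tidy
    table (compound_id, cell_line, screen, replicate, dose_uM,
    response_pct) with multiplicative lognormal noise per well.
    """
    rng = _rng(config.seed, _CONFIRM_STREAM)
    replicates = {1: 1, 2: 2}
    rows = []
    for truth in truths:
        for screen, n_rep in replicates.items():
            for dose in CONFIRMATION_DOSES_UM:
                clean = truth.survival_at(dose)
                factors = _noise(rng, config.well_noise_cv, n_rep)
                for rep, f in enumerate(factors, start=1):
                    rows.append(
                        (truth.compound_id, truth.cell_line_id, screen, rep, dose, clean * f)
                    )
    return pd.DataFrame(
        rows,
        columns=["compound_id", "cell_line", "screen", "replicate", "dose_uM", "response_pct"],
    )


def noise_free(config: GeneratorConfig) -> GeneratorConfig:
    """A copy of ``config`` with every stochastic element switched off."""
    return replace(
        config,
        well_noise_cv=0.0,
        background_inhibition_sd=0.0,
    )
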