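"""Assay-quality statistics and gates: Z' factor, %CV, QC-compound acceptance.

The Z' (Z-prime) factor summarises how well a plate separates its negative
(MAX-signal) and positive (MIN-signal) controls:

    Z' = 1 - 3 * (sd_n + sd_p) / (mean_n - mean_p)

In this growth-inhibition assay the DMSO vehicle wells are the negative
(MAX) group and QC-positive inhibitor wells the positive (MIN) group.
Classification: Z' = 1 ideal; 0.5 <= Z' < 1 excellent; 0 <= Z' < 0.5
marginal but acceptable; Z' < 0 unacceptable.

%CV = 100 * sd / mean measures replicate-well reproducibility; the plate
gate is %CV < 25. Sample (n-1) standard deviations are used throughout —
control groups are small (4-8 wells).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .plate_model import ScreenDataset, WellRole

#: Plate gates.
ZPRIME_GATE = 0.5
CV_GATE = 25.0

#: QC-compound acceptance defaults: a positive must inhibit > 70% at the
#: screening dose under estrogen and must not be estrogen-specific (gap
#: between conditions <= 25 percentage points); a negative must inhibit
#: <= 10% in both conditions.
QC_POSITIVE_MIN_INHIBITION = 70.0
QC_SPECIFICITY_MAX_GAP = 25.0
QC_NEGATIVE_MAX_INHIBITION = 10.0
SCREEN_DOSE_UM = 10.0


class QCError(ValueError):
    """Insufficient or inconsistent control data."""


def _sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1))


@dataclass(frozen=True)
class ZPrimeResult:
    value: float
    classification: str  # ideal | excellent | marginal | unacceptable

    @property
    def passed(self) -> bool:
        return self.value >= ZPRIME_GATE


def classify_zprime(value: float) -> str:
    if value == 1.0:
        return "ideal"
    if 0.5 <= value < 1.0:
        return "excellent"
    if 0.0 <= value < 0.5:
        return "marginal"
    return "unacceptable"


def zprime(mu_n: float, sd_n: float, mu_p: float, sd_p: float) -> ZPrimeResult:
    """Z' factor from control-group summary statistics.

    ``mu_n``/``sd_n`` describe the negative (MAX-signal) controls,
    ``mu_p``/``sd_p`` the positive (MIN-signal) controls. Raises
    :class:`QCError` if the controls are inverted (mu_n <= mu_p).
    """
    if sd_n < 0 or sd_p < 0:
        raise QCError("standard deviations must be non-negative")
    if mu_n <= mu_p:
        raise QCError(
            f"controls inverted: negative (MAX) mean {mu_n} <= positive (MIN) mean {mu_p}"
        )
    value = 1.0 - 3.0 * (sd_n + sd_p) / (mu_n - mu_p)
    return ZPrimeResult(value=value, classification=classify_zprime(value))


def zprime_from_wells(
    negative: Sequence[float], positive: Sequence[float]
) -> ZPrimeResult:
    """Z' from the raw control-well values of one plate."""
    neg = np.asarray(negative, dtype=float)
    pos = np.asarray(positive, dtype=float)
    if len(neg) < 2 or len(pos) < 2:
        raise QCError(
            f"need >= 2 wells per control group, got {len(neg)} negative / {len(pos)} positive"
        )
    return zprime(float(neg.mean()), _sd(neg), float(pos.mean()), _sd(pos))


@dataclass(frozen=True)
class CVResult:
    value: float

    @property
    def passed(self) -> bool:
        return self.value < CV_GATE


def percent_cv(values: Sequence[float]) -> CVResult:
    """%CV = 100 * sample sd / mean of replicate wells; gate < 25."""
    arr = np.asarray(values, dtype=float)
    if len(arr) < 2:
        raise QCError(f"need >= 2 values for %CV, got {len(arr)}")
    mean = float(arr.mean())
    if mean == 0.0:
        raise QCError("%CV undefined: mean of values is zero")
    return CVResult(value=100.0 * _sd(arr) / mean)


# ---------------------------------------------------------------------------
# QC-compound acceptance (titration screen)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QCAcceptance:
    compound_id: str
    role: str  # "positive" | "negative"
    accepted: bool
    inhibition_vehicle: float
    inhibition_estrogen: float
    dose_used_uM: float
    reasons: tuple[str, ...]


def _inhibition_at_nearest_dose(
    series: pd.DataFrame, dose_uM: float
) -> tuple[float, float]:
    """Mean % inhibition (100 - % survival) at the grid dose nearest ``dose_uM``."""
    doses = np.sort(series["dose_uM"].unique())
    if len(doses) == 0:
        raise QCError("empty dose series")
    nearest = float(doses[np.argmin(np.abs(np.log(doses) - np.log(dose_uM)))])
    at = series[series["dose_uM"] == nearest]
    return 100.0 - float(at["response_pct"].mean()), nearest


def qc_compound_acceptance(
    titration: pd.DataFrame,
    role: str,
    compound_id: Optional[str] = None,
    dose_uM: float = SCREEN_DOSE_UM,
    positive_min_inhibition: float = QC_POSITIVE_MIN_INHIBITION,
    specificity_max_gap: float = QC_SPECIFICITY_MAX_GAP,
    negative_max_inhibition: float = QC_NEGATIVE_MAX_INHIBITION,
) -> QCAcceptance:
    """Accept or reject a QC compound from its two-condition titration.

    ``titration`` is tidy (condition, dose_uM, replicate, response_pct) for
    one compound. A positive is accepted iff it inhibits more than
    ``positive_min_inhibition``% at the screening dose under estrogen AND
    the effect is not estrogen-specific (|estrogen - vehicle| inhibition
    gap within ``specificity_max_gap`` points) — estrogen-specific
    inhibitors behave like selective ER modulators and cannot anchor the
    assay floor across conditions. A negative is accepted iff inhibition
    stays within ``negative_max_inhibition``% in both conditions.
    """
    if role not in ("positive", "negative"):
        raise QCError(f"role must be 'positive' or 'negative', got {role!r}")
    if compound_id is None:
        ids = titration.get("compound_id")
        compound_id = str(ids.iloc[0]) if ids is not None and len(ids) else "<qc>"
    inhibition = {}
    dose_used = dose_uM
    for condition in ("vehicle", "estrogen"):
        sub = titration[titration["condition"] == condition]
        if sub.empty:
            raise QCError(f"{compound_id}: no titration data for condition {condition!r}")
        inhibition[condition], dose_used = _inhibition_at_nearest_dose(sub, dose_uM)
    reasons: list[str] = []
    if role == "positive":
        if inhibition["estrogen"] <= positive_min_inhibition:
            reasons.append(
                f"estrogen-condition inhibition {inhibition['estrogen']:.1f}% <= "
                f"{positive_min_inhibition}% at {dose_used:g} µM"
            )
        if abs(inhibition["estrogen"] - inhibition["vehicle"]) > specificity_max_gap:
            reasons.append(
                "estrogen-specific response: inhibition gap "
                f"{abs(inhibition['estrogen'] - inhibition['vehicle']):.1f} > "
                f"{specificity_max_gap} points between conditions"
            )
    else:
        for condition in ("vehicle", "estrogen"):
            if inhibition[condition] > negative_max_inhibition:
                reasons.append(
                    f"{condition}-condition inhibition {inhibition[condition]:.1f}% > "
                    f"{negative_max_inhibition}%"
                )
    return QCAcceptance(
        compound_id=compound_id,
        role=role,
        accepted=not reasons,
        inhibition_vehicle=inhibition["vehicle"],
        inhibition_estrogen=inhibition["estrogen"],
        dose_used_uM=dose_used,
        reasons=tuple(reasons),
    )


# ---------------------------------------------------------------------------
# Whole-screen QC report
# ---------------------------------------------------------------------------

QC_REPORT_COLUMNS = [
    "plate_id",
    "cell_line",
    "condition",
    "group",
    "metric",
    "value",
    "classification",
    "passed",
]


def screen_qc_report(dataset: ScreenDataset) -> pd.DataFrame:
    """Per-plate Z' and %CV table for every control group of a screen.

    For each raw plate: one Z' row per QC-positive compound (DMSO wells as
    the negative/MAX group, that compound's wells as the positive/MIN
    group) and one %CV row per control group (DMSO and each QC compound).
    Z' and %CV are scale-invariant, so raw counts are used directly;
    normalizing first would not change any value.
    """
    rows = []
    by_layout = {pid: layout for pid, layout in dataset.layouts.items()}
    for (layout_id, line), pair in dataset.pairing.items():
        layout = by_layout[layout_id]
        dmso_addrs = layout.wells_with_role(WellRole.VEHICLE)
        qc_groups: dict[str, tuple[str, list]] = {}
        for addr, entry in layout.wells.items():
            if entry.role in (WellRole.QC_POSITIVE, WellRole.QC_NEGATIVE):
                name = entry.compound_id or entry.role.value
                qc_groups.setdefault(name, (entry.role.value, []))[1].append(addr)
        for plate in pair:
            counts = plate.unflagged_counts()
            dmso = [counts[a] for a in dmso_addrs if a in counts]
            cv = percent_cv(dmso)
            rows.append(
                (plate.plate_id, line, plate.condition, "DMSO", "percent_cv",
                 cv.value, "negative_control", cv.passed)
            )
            for name, (role, addrs) in sorted(qc_groups.items()):
                vals = [counts[a] for a in addrs if a in counts]
                cv = percent_cv(vals)
                rows.append(
                    (plate.plate_id, line, plate.condition, name, "percent_cv",
                     cv.value, role, cv.passed)
                )
                if role == WellRole.QC_POSITIVE.value:
                    z = zprime_from_wells(dmso, vals)
                    rows.append(
                        (plate.plate_id, line, plate.condition, name, "zprime",
                         z.value, z.classification, z.passed)
                    )
    return pd.DataFrame(rows, columns=QC_REPORT_COLUMNS)


def qc_report_summary(report: pd.DataFrame) -> str:
    """Human-readable gate summary of a screen QC report."""
    z = report[report["metric"] == "zprime"]
    cv = report[report["metric"] == "percent_cv"]
    neg_cv = cv[cv["classification"].isin(["negative_control", WellRole.QC_NEGATIVE.value])]
    lines = [
        f"Z' factor: {len(z)} plate/control pairings, min {z['value'].min():.3f}, "
        f"{int(z['passed'].sum())}/{len(z)} >= {ZPRIME_GATE}",
        f"%CV: {len(cv)} control groups, max {cv['value'].max():.2f}%, "
        f"{int(cv['passed'].sum())}/{len(cv)} < {CV_GATE}%",
        f"%CV (negative controls only): max {neg_cv['value'].max():.2f}%",
    ]
    return "\n".join(lines)
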