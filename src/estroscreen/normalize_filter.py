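"""Per-plate normalization and the triage filters that precede hit calling.

Order of operations (permuting the first two changes nothing on flag-free
data, but flags always win):

1. image-flag exclusion — wells the imaging QC marked bad never enter any
   statistic;
2. control-outlier removal — DMSO vehicle wells beyond 3 SD of the plate's
   DMSO mean are dropped (single pass, sample SD);
3. normalization — every remaining well is divided by the retained DMSO
   mean, so the retained controls average exactly 1;
4. vehicle-toxicity filter — compounds whose normalized vehicle-condition
   viability falls below 0.5 are excluded per cell line (they are toxic
   regardless of estrogen and cannot inform estrogen-driven inhibition).

The media wells are background checks only; they are normalized like any
other well but never enter the control mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .plate_model import PlateLayout, RawPlate, WellAddress, WellRole

#: Control wells beyond this many SDs of the DMSO mean are outliers.
OUTLIER_K = 3.0
#: Normalized vehicle viability below this excludes a compound (strict <).
TOXICITY_CUTOFF = 0.5


class NormalizationError(ValueError):
    """Too few usable control wells to normalize a plate."""


def remove_control_outliers(
    control_counts: Sequence[float], k: float = OUTLIER_K
) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass 3-SD outlier removal on vehicle-control wells.

    Mean and sample SD are computed once on all wells; wells with
    |x - mean| > k*sd are removed. Returns (retained, removed) arrays whose
    concatenation is the input. With zero variance nothing is removed.
    """
    arr = np.asarray(control_counts, dtype=float)
    if len(arr) < 3:
        raise NormalizationError(
            f"need >= 3 control wells for outlier removal, got {len(arr)}"
        )
    mean = arr.mean()
    sd = arr.std(ddof=1)
    outlier = np.abs(arr - mean) > k * sd
    return arr[~outlier], arr[outlier]


@dataclass
class NormalizedPlate:
    """One plate's counts divided by its retained DMSO-control mean."""

    plate_id: str
    cell_line_id: str
    condition: str
    normalized: dict[WellAddress, float]
    control_mean: float
    control_sd: float
    n_controls_retained: int
    n_controls_removed: int
    n_wells_flagged: int

    def to_frame(self, layout: PlateLayout) -> pd.DataFrame:
        rows = []
        for addr in sorted(self.normalized, key=lambda a: (a.row, a.column)):
            entry = layout.wells[addr]
            rows.append(
                {
                    "plate_id": self.plate_id,
                    "cell_line": self.cell_line_id,
                    "condition": self.condition,
                    "well": str(addr),
                    "role": entry.role.value,
                    "compound_id": entry.compound_id or "",
                    "normalized_value": self.normalized[addr],
                }
            )
        return pd.DataFrame(rows)


def normalize_plate(
    raw: RawPlate, layout: PlateLayout, outlier_k: float = OUTLIER_K
) -> NormalizedPlate:
    """Normalize a plate to the mean of its retained DMSO vehicle wells.

    Flagged wells are excluded before anything else and are absent from
    the output map, as are DMSO wells removed as outliers. Raises
    :class:`NormalizationError` when fewer than 3 unflagged DMSO wells
    survive outlier removal.
    """
    counts = raw.unflagged_counts()
    dmso_addrs = [a for a in layout.wells_with_role(WellRole.VEHICLE) if a in counts]
    if len(dmso_addrs) < 3:
        raise NormalizationError(
            f"{raw.plate_id}: only {len(dmso_addrs)} unflagged DMSO wells; need >= 3"
        )
    dmso_values = np.array([counts[a] for a in dmso_addrs], dtype=float)
    # same single-pass rule as remove_control_outliers, tracked per address
    outlier = np.abs(dmso_values - dmso_values.mean()) > outlier_k * dmso_values.std(ddof=1)
    retained = dmso_values[~outlier]
    removed_addrs = {a for a, bad in zip(dmso_addrs, outlier) if bad}
    if len(retained) < 3:
        raise NormalizationError(
            f"{raw.plate_id}: only {len(retained)} DMSO wells retained after "
            f"outlier removal; need >= 3"
        )
    mean = float(retained.mean())
    if mean <= 0:
        raise NormalizationError(f"{raw.plate_id}: non-positive DMSO control mean {mean}")
    normalized = {
        a: c / mean for a, c in counts.items() if a not in removed_addrs
    }
    return NormalizedPlate(
        plate_id=raw.plate_id,
        cell_line_id=raw.cell_line_id,
        condition=raw.condition,
        normalized=normalized,
        control_mean=mean,
        control_sd=float(retained.std(ddof=1)) if len(retained) > 1 else 0.0,
        n_controls_retained=len(retained),
        n_controls_removed=len(removed_addrs),
        n_wells_flagged=len(raw.flagged_wells()),
    )


#: Status labels assigned by the toxicity filter.
STATUS_RETAINED = "retained"
STATUS_EXCLUDED_TOXIC = "excluded_toxicity"
STATUS_UNEVALUABLE = "unevaluable"


def vehicle_toxicity_filter(
    viability: pd.DataFrame, cutoff: float = TOXICITY_CUTOFF
) -> pd.DataFrame:
    """Per-(compound, cell line) vehicle-toxicity triage.

    ``viability`` needs columns compound_id, cell_line, alpha (normalized
    vehicle-condition viability; the mean over replicates if several, NaN
    if unmeasured). Returns the table with a ``status`` column: excluded
    iff alpha < cutoff (strict, so exactly 0.5 is retained), unevaluable
    if alpha is missing. Exclusion is per cell line.
    """
    out = viability.copy()
    alpha = out["alpha"].astype(float)
    status = np.where(alpha < cutoff, STATUS_EXCLUDED_TOXIC, STATUS_RETAINED)
    status = np.where(alpha.isna(), STATUS_UNEVALUABLE, status)
    out["status"] = status
    n = len(out)
    parts = out["status"].value_counts()
    assert parts.sum() == n, "toxicity filter must partition its input"
    return out
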