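"""4PL dose-response fitting, IC50 adjudication, and lead-compound triage.

The confirmation screen measures % survival over a 5-point 1:5 dilution
series from 10 µM, once in singlet (screen 1) and once in duplicate
(screen 2); the two screens are averaged with equal weight (replicates
within a screen first) and the average is fit with the four-parameter
logistic (Hill) model, the standard "log(inhibitor) vs. response —
variable slope" parameterization:

    y(c) = B + (T - B) / (1 + (c / IC50)^h)

with bottom B, top T (% survival), Hill slope h > 0 (response falls as
dose rises), and IC50 fit on the log10 scale. Fitting is bounded
nonlinear least squares (0 <= B, T <= 150; 0.2 <= h <= 5;
log10 IC50 in [-4, 3]) with a crossing-point initialization and three
perturbed restarts on failure.

An attempted fit is then adjudicated into one of four outcomes:

* ``nd`` — not determinable: the optimizer failed, the fitted span
  T - B is under 25 percentage points, or the IC50 is too uncertain
  (standard error of log10 IC50 above 1/ln 10, i.e. >100% relative
  error on the concentration scale);
* ``above_range`` — maximal observed inhibition stays under 50%, so the
  IC50 lies beyond the top dose; displayed ">{top dose}";
* ``extrapolated_low`` — the fitted IC50 falls below the lowest dose;
  the numeric value is still reported, flagged as an extrapolation;
* ``converged`` — a numeric in-range IC50.

Compounds with a numeric IC50 <= 1 µM in a cell line are leads for that
line; ``nd`` and ">x" outcomes are never leads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

LEAD_IC50_CUTOFF_UM = 1.0
ND = "ND"

#: Adjudication constants.
MIN_SPAN_PCT = 25.0
MIN_MAX_INHIBITION_PCT = 50.0
MAX_LOG_IC50_SE = 1.0 / math.log(10.0)  # 100% relative error on IC50

#: Fit bounds: (bottom, top, hill, log10_ic50).
FIT_LOWER = (0.0, 0.0, 0.2, -4.0)
FIT_UPPER = (150.0, 150.0, 5.0, 3.0)


class DoseResponseError(ValueError):
    pass


def four_pl(
    c: Union[float, np.ndarray],
    bottom: float,
    top: float,
    hill: float,
    log10_ic50: float,
) -> Union[float, np.ndarray]:
    """Four-parameter logistic % survival at dose ``c`` (µM, > 0)."""
    arr = np.asarray(c, dtype=float)
    if np.any(arr <= 0):
        raise DoseResponseError(f"doses must be positive, got {c!r}")
    # evaluated in log space for numerical stability at extreme ratios
    log_ratio = hill * (np.log10(arr) - log10_ic50)
    out = bottom + (top - bottom) / (1.0 + 10.0 ** log_ratio)
    return float(out) if np.isscalar(c) else out


@dataclass(frozen=True)
class DoseSeries:
    """Averaged % survival over a strictly decreasing dose series."""

    compound_id: str
    cell_line_id: str
    doses: tuple[float, ...]
    responses: tuple[float, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        if len(d) != len(r):
            raise DoseResponseError("doses and responses differ in length")
        if np.any(d <= 0):
            raise DoseResponseError("doses must be positive")
        if np.any(np.diff(d) >= 0):
            raise DoseResponseError("doses must be strictly decreasing")
        if np.any(r < 0):
            raise DoseResponseError("responses must be non-negative")


def average_screens(
    screen1: Sequence,
    screen2: Sequence,
    doses1: Optional[Sequence[float]] = None,
    doses2: Optional[Sequence[float]] = None,
) -> np.ndarray:
    """Equal-weight average of two screens at a shared dose grid.

    Each screen is a (n_doses,) or (n_replicates, n_doses) array; a
    screen's replicates are averaged first, then the two screen means are
    averaged with equal weight so unequal replication (singlet screen 1,
    duplicate screen 2) does not tilt the result. Dose grids, when given,
    must match.
    """
    s1 = np.atleast_2d(np.asarray(screen1, dtype=float))
    s2 = np.atleast_2d(np.asarray(screen2, dtype=float))
    if s1.shape[1] != s2.shape[1]:
        raise DoseResponseError(
            f"mismatched dose grids: {s1.shape[1]} vs {s2.shape[1]} doses"
        )
    if doses1 is not None and doses2 is not None:
        d1 = np.asarray(doses1, dtype=float)
        d2 = np.asarray(doses2, dtype=float)
        if d1.shape != d2.shape or not np.allclose(d1, d2):
            raise DoseResponseError("mismatched dose grids between screens")
    return (s1.mean(axis=0) + s2.mean(axis=0)) / 2.0


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class DoseResponseFit:
    compound_id: str
    cell_line_id: str
    bottom: float
    top: float
    hill: float
    log10_ic50: float
    rss: float
    se_log10_ic50: float
    status: str  # converged | nd | above_range | extrapolated_low
    ic50_display: str
    message: str = ""

    @property
    def ic50_uM(self) -> float:
        return 10.0 ** self.log10_ic50

    @property
    def has_numeric_ic50(self) -> bool:
        return self.status in ("converged", "extrapolated_low")


def _initial_guess(log_doses: np.ndarray, responses: np.ndarray) -> list[float]:
    top0 = float(responses.max())
    bottom0 = float(responses.min())
    mid = 0.5 * (top0 + bottom0)
    # first crossing of the half-height, walking from low to high dose
    order = np.argsort(log_doses)
    ld, r = log_doses[order], responses[order]
    log_ic50_0 = float(ld.mean())
    for i in range(1, len(r)):
        if (r[i - 1] - mid) * (r[i] - mid) <= 0 and r[i - 1] != r[i]:
            frac = (r[i - 1] - mid) / (r[i - 1] - r[i])
            log_ic50_0 = float(ld[i - 1] + frac * (ld[i] - ld[i - 1]))
            break
    guess = [bottom0, top0, 1.0, log_ic50_0]
    return [min(max(g, lo), hi) for g, lo, hi in zip(guess, FIT_LOWER, FIT_UPPER)]


def _fit_once(
    log_doses: np.ndarray, responses: np.ndarray, p0: list[float]
) -> tuple[np.ndarray, np.ndarray]:
    def model(ld, bottom, top, hill, log10_ic50):
        return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (ld - log10_ic50)))

    popt, pcov = curve_fit(
        model,
        log_doses,
        responses,
        p0=p0,
        bounds=(FIT_LOWER, FIT_UPPER),
        maxfev=20000,
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    return popt, pcov


def fit_4pl(
    series: DoseSeries,
    doses: Optional[Sequence[float]] = None,
    responses: Optional[Sequence[float]] = None,
) -> DoseResponseFit:
    """Bounded least-squares 4PL fit of an averaged dose series.

    Accepts a :class:`DoseSeries` (or raw arrays for convenience), runs
    the crossing-point initialization plus up to three perturbed restarts,
    and returns the adjudicated :class:`DoseResponseFit`.
    """
    if doses is None:
        doses = series.doses
        responses = series.responses
    d = np.asarray(doses, dtype=float)
    r = np.asarray(responses, dtype=float)
    if len(d) < 4:
        raise DoseResponseError(f"need >= 4 dose points to fit 4 parameters, got {len(d)}")
    failed = DoseResponseFit(
        compound_id=series.compound_id,
        cell_line_id=series.cell_line_id,
        bottom=float("nan"),
        top=float("nan"),
        hill=float("nan"),
        log10_ic50=float("nan"),
        rss=float("nan"),
        se_log10_ic50=float("inf"),
        status="nd",
        ic50_display=ND,
    )
    if np.allclose(r, r[0]):
        failed.message = "no dose dependence"
        return failed
    log_d = np.log10(d)
    p0 = _initial_guess(log_d, r)
    starts = [p0]
    for d_log_ic50, h0 in ((0.5, 0.5), (-0.5, 2.0), (0.0, 3.0)):
        alt = list(p0)
        alt[2] = min(max(h0, FIT_LOWER[2]), FIT_UPPER[2])
        alt[3] = min(max(p0[3] + d_log_ic50, FIT_LOWER[3]), FIT_UPPER[3])
        starts.append(alt)
    best: Optional[tuple[np.ndarray, np.ndarray, float]] = None
    errors: list[str] = []
    for start in starts:
        try:
            popt, pcov = _fit_once(log_d, r, start)
        except (RuntimeError, ValueError) as exc:
            errors.append(str(exc))
            continue
        rss = float(np.sum((four_pl(d, *popt) - r) ** 2))
        if best is None or rss < best[2] - 1e-12:
            best = (popt, pcov, rss)
        if best is not None and start is starts[0]:
            break  # primary start converged; restarts are for failures only
    if best is None:
        failed.message = "; ".join(errors) or "optimizer failed"
        return failed
    popt, pcov, rss = best
    with np.errstate(invalid="ignore"):
        se = float(np.sqrt(pcov[3, 3])) if np.all(np.isfinite(pcov)) else float("inf")
    fit = DoseResponseFit(
        compound_id=series.compound_id,
        cell_line_id=series.cell_line_id,
        bottom=float(popt[0]),
        top=float(popt[1]),
        hill=float(popt[2]),
        log10_ic50=float(popt[3]),
        rss=rss,
        se_log10_ic50=se,
        status="converged",
        ic50_display="",
    )
    return adjudicate_ic50(fit, d, r)


def adjudicate_ic50(
    fit: DoseResponseFit, doses: Sequence[float], responses: Sequence[float]
) -> DoseResponseFit:
    """Classify a completed fit attempt into nd / above_range /
    extrapolated_low / converged and set its display token.

    Insufficient inhibition (max observed inhibition < 50%) is checked
    before the span/uncertainty ND rules: a shallow curve whose floor the
    dose range never reaches is ">top dose", not ND.
    """
    d = np.asarray(doses, dtype=float)
    r = np.asarray(responses, dtype=float)
    if fit.status == "nd" or not np.isfinite(fit.log10_ic50):
        fit.status = "nd"
        fit.ic50_display = ND
        return fit
    max_inhibition = 100.0 - float(r.min())
    if max_inhibition < MIN_MAX_INHIBITION_PCT:
        fit.status = "above_range"
        fit.ic50_display = f">{d.max():g}"
        fit.message = f"max observed inhibition {max_inhibition:.1f}% < {MIN_MAX_INHIBITION_PCT}%"
        return fit
    span = fit.top - fit.bottom
    if span < MIN_SPAN_PCT:
        fit.status = "nd"
        fit.ic50_display = ND
        fit.message = f"fitted span {span:.1f} < {MIN_SPAN_PCT} percentage points"
        return fit
    if fit.se_log10_ic50 > MAX_LOG_IC50_SE:
        fit.status = "nd"
        fit.ic50_display = ND
        fit.message = (
            f"log10 IC50 SE {fit.se_log10_ic50:.2f} > {MAX_LOG_IC50_SE:.2f} "
            "(>100% relative error)"
        )
        return fit
    ic50 = fit.ic50_uM
    if ic50 < d.min():
        fit.status = "extrapolated_low"
        fit.ic50_display = f"{ic50:.4g}"
        fit.message = f"IC50 {ic50:.4g} µM below lowest dose {d.min():g} µM (extrapolated)"
        return fit
    fit.status = "converged"
    fit.ic50_display = f"{ic50:.4g}"
    return fit


def fit_confirmation_table(confirmation: pd.DataFrame) -> list[DoseResponseFit]:
    """Average the two screens and fit every (compound, cell line) series.

    ``confirmation`` is the tidy two-screen table (compound_id, cell_line,
    screen, replicate, dose_uM, response_pct).
    """
    fits = []
    for (cid, line), sub in confirmation.groupby(["compound_id", "cell_line"], sort=True):
        screens = sorted(sub["screen"].unique())
        if len(screens) != 2:
            raise DoseResponseError(
                f"{cid}/{line}: expected 2 screens, found {screens}"
            )
        per_screen = []
        grids = []
        for s in screens:
            pivot = sub[sub["screen"] == s].pivot_table(
                index="replicate", columns="dose_uM", values="response_pct"
            )
            pivot = pivot.sort_index(axis=1, ascending=False)
            grids.append(pivot.columns.to_numpy(dtype=float))
            per_screen.append(pivot.to_numpy(dtype=float))
        averaged = average_screens(per_screen[0], per_screen[1], grids[0], grids[1])
        series = DoseSeries(
            compound_id=str(cid),
            cell_line_id=str(line),
            doses=tuple(grids[0]),
            responses=tuple(averaged),
        )
        fits.append(fit_4pl(series))
    return fits


# ---------------------------------------------------------------------------
# Lead designation and per-line categorization
# ---------------------------------------------------------------------------


def parse_ic50_outcome(value) -> tuple[str, Optional[float]]:
    """Parse a printed IC50 entry: a number, ``"ND"``, or ``">x"``.

    Returns (kind, numeric value or None) with kind in
    {"numeric", "nd", "above_range"}.
    """
    if isinstance(value, (int, float)) and not (
        isinstance(value, float) and math.isnan(value)
    ):
        return ("numeric", float(value))
    text = str(value).strip()
    if not text or text.upper() == ND:
        return ("nd", None)
    if text.startswith(">"):
        return ("above_range", None)
    return ("numeric", float(text))


def designate_leads(
    outcomes: pd.DataFrame, cutoff_uM: float = LEAD_IC50_CUTOFF_UM
) -> pd.DataFrame:
    """Per-line lead flags and the cross-line category of each compound.

    ``outcomes`` is tidy with columns compound_id, cell_line, ic50 (number,
    "ND", or ">x"). A compound is a lead in a line iff its IC50 there is
    numeric and <= ``cutoff_uM``; "ND" and ">x" never lead regardless of
    any number printed after ">". Returns one row per compound with
    ``ic50_<line>``, ``lead_<line>``, ``lead_any``, and ``category``
    (``<line>_only`` / ``both`` / ``neither`` for two lines).
    """
    lines = sorted(outcomes["cell_line"].astype(str).unique())
    rows = {}
    for rec in outcomes.itertuples(index=False):
        entry = rows.setdefault(rec.compound_id, {"compound_id": rec.compound_id})
        kind, number = parse_ic50_outcome(rec.ic50)
        line = str(rec.cell_line)
        entry[f"ic50_{line}"] = rec.ic50
        entry[f"lead_{line}"] = kind == "numeric" and number is not None and number <= cutoff_uM
    table = pd.DataFrame(list(rows.values()))
    lead_cols = [f"lead_{line}" for line in lines]
    for col in lead_cols:
        if col not in table.columns:
            table[col] = False
        table[col] = table[col].map(lambda v: bool(v) if pd.notna(v) else False)
    table["lead_any"] = table[lead_cols].any(axis=1)

    def category(row) -> str:
        member = [line for line in lines if row[f"lead_{line}"]]
        if not member:
            return "neither"
        if len(member) == len(lines) and len(lines) > 1:
            return "both"
        if len(member) == 1 and len(lines) > 1:
            return f"{member[0]}_only"
        return "+".join(member)

    table["category"] = table.apply(category, axis=1)
    table.attrs["cutoff_uM"] = cutoff_uM
    table.attrs["cell_lines"] = lines
    return table


def categorize_leads(lead_table: pd.DataFrame) -> dict[str, int]:
    """Category counts; a partition of the evaluated compounds."""
    lines = lead_table.attrs.get("cell_lines")
    if lines is None:
        lines = sorted(
            c[len("lead_"):] for c in lead_table.columns
            if c.startswith("lead_") and c != "lead_any"
        )
    categories = [f"{line}_only" for line in lines] + ["both", "neither"]
    counts = {cat: 0 for cat in categories}
    for cat in lead_table["category"]:
        counts[cat] = counts.get(cat, 0) + 1
    assert sum(counts.values()) == len(lead_table)
    return counts


def fits_to_frame(fits: Sequence[DoseResponseFit]) -> pd.DataFrame:
    rows = [
        {
            "compound_id": f.compound_id,
            "cell_line": f.cell_line_id,
            "bottom": f.bottom,
            "top": f.top,
            "hill": f.hill,
            "ic50_uM": f.ic50_uM if f.has_numeric_ic50 else float("nan"),
            "status": f.status,
            "ic50": f.ic50_display,
            "rss": f.rss,
            "message": f.message,
        }
        for f in fits
    ]
    return pd.DataFrame(rows)
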