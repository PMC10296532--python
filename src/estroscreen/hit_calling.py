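"""%E-DI computation, adaptive hit thresholding, and screen summaries.

%E-DI (percent estrogen-driven inhibition) compares a compound's
normalized viability under estrogen (β) with its normalized viability
under vehicle (α) on the paired plates of the same library plate and cell
line. Two algebraic forms exist:

* ``inhibition`` (default): %E-DI = 100 * (1 - β/α) — 0 when estrogen-
  and vehicle-condition growth match, 100 when estrogen-condition growth
  is fully suppressed. This is the form the >70%-inhibition hit rule and
  the screen's scatter plots operate on.
* ``as_printed``: %E-DI = 100 * (β/α) — the relative-survival ratio as
  sometimes written; it is the complement of the inhibition form (the two
  sum to 100).

The form in use is carried in every output so the ambiguity can never be
silent. The hit threshold is adaptive — mean + 2.5 SD of all analyzed
%E-DI values — with an optional fixed override (e.g. 70); hits are strict
exceedances (edi > threshold), and only compounds that survived the
vehicle-toxicity filter are eligible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .normalize_filter import STATUS_RETAINED

EDI_FORMS = ("inhibition", "as_printed")
DEFAULT_THRESHOLD_MULTIPLIER = 2.5


class HitCallingError(ValueError):
    pass


def edi(alpha: float, beta: float, form: str = "inhibition") -> float:
    """%E-DI of one compound from its normalized viabilities.

    ``alpha`` is the vehicle-condition value (must be > 0), ``beta`` the
    estrogen-condition value (>= 0).
    """
    if form not in EDI_FORMS:
        raise HitCallingError(f"unknown %E-DI form {form!r}; expected one of {EDI_FORMS}")
    if alpha <= 0:
        raise HitCallingError(
            f"%E-DI undefined: vehicle-condition viability alpha={alpha} (must be > 0)"
        )
    if beta < 0:
        raise HitCallingError(f"negative estrogen-condition viability beta={beta}")
    ratio = 100.0 * beta / alpha
    return 100.0 - ratio if form == "inhibition" else ratio


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (plate-report convention; Python's
    built-in round is banker's)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass(frozen=True)
class HitThreshold:
    """Adaptive %E-DI hit threshold: mean + multiplier * sample SD.

    ``applied`` is what hit calling uses: the derived value, or a fixed
    override when one is configured. Both are always reported.
    """

    mean_edi: float
    sd_edi: float
    multiplier: float
    override: Optional[float] = None

    @property
    def derived(self) -> float:
        return self.mean_edi + self.multiplier * self.sd_edi

    @property
    def applied(self) -> float:
        return self.derived if self.override is None else self.override


def derive_threshold(
    edi_values: Iterable[float],
    multiplier: float = DEFAULT_THRESHOLD_MULTIPLIER,
    override: Optional[float] = None,
) -> HitThreshold:
    """Mean + ``multiplier`` sample SDs over all analyzed %E-DI values."""
    arr = np.asarray(list(edi_values), dtype=float)
    arr = arr[~np.isnan(arr)]
    if len(arr) < 2:
        raise HitCallingError(f"need >= 2 %E-DI values to derive a threshold, got {len(arr)}")
    return HitThreshold(
        mean_edi=float(arr.mean()),
        sd_edi=float(arr.std(ddof=1)),
        multiplier=multiplier,
        override=override,
    )


EDI_TABLE_COLUMNS = [
    "compound_id",
    "cell_line",
    "alpha",
    "beta",
    "edi",
    "status",
]


def build_edi_table(
    viability: pd.DataFrame, form: str = "inhibition"
) -> pd.DataFrame:
    """Per-(compound, cell line) %E-DI from a paired-viability table.

    ``viability`` needs columns compound_id, cell_line, alpha, beta and a
    ``status`` column from the toxicity filter. %E-DI is computed only for
    retained rows with a usable alpha; others keep NaN. The form is
    recorded in ``DataFrame.attrs['edi_form']``.
    """
    out = viability.copy()
    alpha = out["alpha"].astype(float)
    beta = out["beta"].astype(float)
    ratio = 100.0 * beta / alpha.where(alpha > 0)
    values = 100.0 - ratio if form == "inhibition" else ratio
    eligible = (out["status"] == STATUS_RETAINED) & alpha.gt(0) & beta.notna()
    out["edi"] = values.where(eligible)
    out.attrs["edi_form"] = form
    return out


def call_hits(edi_table: pd.DataFrame, threshold: HitThreshold) -> pd.DataFrame:
    """Flag hits: edi strictly above the applied threshold.

    Only rows with a computed %E-DI (i.e. retained by the toxicity filter)
    are eligible; everything else is ``is_hit = False``.
    """
    cutoff = threshold.applied
    if not np.isfinite(cutoff):
        raise HitCallingError(f"non-finite hit threshold {cutoff}")
    out = edi_table.copy()
    out["threshold"] = cutoff
    out["is_hit"] = out["edi"].gt(cutoff).fillna(False).astype(bool)
    out.attrs = dict(edi_table.attrs)
    return out


def hits_per_line(hit_table: pd.DataFrame) -> dict[str, list[str]]:
    """Sorted hit-compound lists keyed by cell line."""
    out: dict[str, list[str]] = {}
    for line, sub in hit_table.groupby("cell_line"):
        out[str(line)] = sorted(sub.loc[sub["is_hit"], "compound_id"].unique())
    return out


@dataclass(frozen=True)
class ScreenSummary:
    """Headline counts of a primary screen.

    ``n_excluded_toxicity`` counts compounds excluded by the vehicle-
    toxicity filter in at least one cell line; ``n_analyzed`` is the rest,
    so the two partition the library. ``n_hits_total`` is the size of the
    union of the per-line hit sets. Percentages are recomputed from the
    counts and rounded half-away-from-zero to one decimal.
    """

    n_library: int
    n_excluded_toxicity: int
    n_analyzed: int
    n_unevaluable: int
    hits_per_line: Mapping[str, int]
    n_hits_total: int
    edi_form: str
    threshold: HitThreshold

    @property
    def pct_excluded(self) -> float:
        return round_half_away(100.0 * self.n_excluded_toxicity / self.n_library)

    @property
    def pct_analyzed(self) -> float:
        return round_half_away(100.0 * self.n_analyzed / self.n_library)

    @property
    def pct_hits(self) -> float:
        return round_half_away(100.0 * self.n_hits_total / self.n_analyzed)

    def to_text(self) -> str:
        per_line = ", ".join(f"{k}: {v}" for k, v in sorted(self.hits_per_line.items()))
        lines = [
            f"library compounds tested: {self.n_library}",
            f"excluded by vehicle-toxicity filter (any line): "
            f"{self.n_excluded_toxicity} ({self.pct_excluded}%)",
            f"analyzed: {self.n_analyzed} ({self.pct_analyzed}%)",
            f"unevaluable (missing vehicle measurement): {self.n_unevaluable}",
            f"%E-DI form: {self.edi_form}",
            f"hit threshold: derived {self.threshold.derived:.2f} "
            f"(mean {self.threshold.mean_edi:.2f} + {self.threshold.multiplier} x "
            f"SD {self.threshold.sd_edi:.2f}); applied {self.threshold.applied:.2f}",
            f"hits per line: {per_line}",
            f"hits (union over lines): {self.n_hits_total} ({self.pct_hits}%)",
        ]
        return "\n".join(lines)


def summarize_screen(hit_table: pd.DataFrame, threshold: HitThreshold) -> ScreenSummary:
    """Compound-level summary of a completed hit-calling table."""
    from .normalize_filter import STATUS_EXCLUDED_TOXIC, STATUS_UNEVALUABLE

    compounds = hit_table["compound_id"].unique()
    by_compound = hit_table.groupby("compound_id")["status"]
    excluded = by_compound.apply(lambda s: (s == STATUS_EXCLUDED_TOXIC).any())
    unevaluable = by_compound.apply(
        lambda s: (s == STATUS_UNEVALUABLE).all()
    )
    n_excluded = int((excluded & ~unevaluable).sum())
    n_unevaluable = int(unevaluable.sum())
    per_line = {k: len(v) for k, v in hits_per_line(hit_table).items()}
    union_hits = set(hit_table.loc[hit_table["is_hit"], "compound_id"])
    return ScreenSummary(
        n_library=len(compounds),
        n_excluded_toxicity=n_excluded,
        n_analyzed=len(compounds) - n_excluded - n_unevaluable,
        n_unevaluable=n_unevaluable,
        hits_per_line=per_line,
        n_hits_total=len(union_hits),
        edi_form=str(hit_table.attrs.get("edi_form", "inhibition")),
        threshold=threshold,
    )
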