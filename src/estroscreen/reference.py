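"""Reference confirmation-screen outcomes used as triage inputs.

The confirmation qHTS this pipeline re-implements reported, for each
cherry-picked compound, an IC50 outcome per endometrial stromal cell line
(1455 and 1458): a numeric IC50 in µM, ``"ND"`` (not determinable), or a
``">x"`` token when inhibition never reached half-maximum within the dose
range. The published lead table is embedded here verbatim as the standard
input for lead-triage validation and for seeding simulated confirmation
screens with realistic potencies.
"""

from __future__ import annotations

import pandas as pd

CELL_LINES = ("1455", "1458")

#: (compound id, generic name, compound group, IC50 1455, IC50 1458).
#: IC50 entries are strings exactly as reported: numeric µM, "ND", or ">x".
CONFIRMED_LEAD_IC50S: tuple[tuple[str, str, str, str, str], ...] = (
    ("SN01006330", "7,8-Dimethoxyflavone", "anti-inflammatory", "0.08", "0.19"),
    ("SN01005561", "Aminothiazole", "anti-microbial", "0.12", "2.08"),
    ("SN01005320", "Benazepril HCl", "anti-hypertensive", "9.37", "0.06"),
    ("SN01005071", "Ceftibuten", "anti-microbial", "2.29", "0.07"),
    ("SN00852779", "Chlordiazepoxide", "anti-depressant", "0.02", "0.08"),
    ("SN01005451", "Chloroquinalol", "anti-microbial", ">20", "0.08"),
    ("SN01006117", "Cytidine triphosphate disodium", "anti-inflammatory", "0.02", "0.08"),
    ("SN01005419", "Editol", "anti-inflammatory", "ND", "0.87"),
    ("SN01004366", "Hydroxyzine Pamoate", "anti-histamine", "0.02", "ND"),
    ("SN01004587", "Indoprofen", "anti-inflammatory", "0.02", "0.001"),
    ("SN01004583", "Ketotifen Fumarate", "anti-histamine", "0.22", "ND"),
    ("SN01005061", "Pantoprazole", "proton pump inhibitor", "0.19", "0.37"),
    ("SN01005391", "Pregabalin", "anti-inflammatory", "0.08", "0.08"),
    ("SN01004486", "Promazine HCl", "anti-psychotic", "0.02", "0.15"),
    ("SN01005316", "Repaglinide", "anti-diabetic", ">20", "0.07"),
    ("SN01005445", "Sildenafil Citrate", "anti-inflammatory", "1.88", "0.96"),
    ("SN01004511", "Spectinomycin HCl", "anti-microbial", "0.02", "ND"),
)

#: Headline primary-screen counts of the same study: library size, compounds
#: removed by the vehicle-toxicity triage, compounds analyzed, and hits
#: taken forward (union over the two cell lines).
PRIMARY_SCREEN_COUNTS = {
    "n_library": 3517,
    "n_excluded_toxicity": 283,
    "n_analyzed": 3234,
    "n_hits_total": 55,
    "hits_per_line": {"1455": 19, "1458": 36},
}


def lead_ic50_frame() -> pd.DataFrame:
    """The reference lead table, wide: one row per compound."""
    return pd.DataFrame(
        list(CONFIRMED_LEAD_IC50S),
        columns=["compound_id", "generic_name", "compound_group",
                 f"ic50_{CELL_LINES[0]}", f"ic50_{CELL_LINES[1]}"],
    )


def lead_ic50_outcomes() -> pd.DataFrame:
    """The reference lead table, tidy: (compound_id, cell_line, ic50)."""
    rows = []
    for cid, _name, _group, ic50_a, ic50_b in CONFIRMED_LEAD_IC50S:
        rows.append({"compound_id": cid, "cell_line": CELL_LINES[0], "ic50": ic50_a})
        rows.append({"compound_id": cid, "cell_line": CELL_LINES[1], "ic50": ic50_b})
    return pd.DataFrame(rows)


def reference_ic50(compound_id: str, cell_line: str) -> float:
    """Numeric reference IC50 (µM) for one compound and line."""
    for cid, _name, _group, a, b in CONFIRMED_LEAD_IC50S:
        if cid == compound_id:
            value = {CELL_LINES[0]: a, CELL_LINES[1]: b}[cell_line]
            return float(value)
    raise KeyError(f"no reference entry for {compound_id!r}")
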