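"""4PL model, fitting, IC50 adjudication, and lead triage."""

import math

import numpy as np
import pandas as pd
import pytest

from estroscreen.dose_response import (
    DoseResponseError,
    DoseSeries,
    average_screens,
    categorize_leads,
    designate_leads,
    fit_4pl,
    fit_confirmation_table,
    four_pl,
    parse_ic50_outcome,
)
from estroscreen.reference import lead_ic50_outcomes
from estroscreen.synthetic_screen import (
    CONFIRMATION_DOSES_UM,
    DoseResponseTruth,
    GeneratorConfig,
    simulate_confirmation_screen,
)

DOSES = tuple(CONFIRMATION_DOSES_UM)


def _series(responses, doses=DOSES):
    return DoseSeries("c", "1455", tuple(doses), tuple(responses))


# ---------------------------------------------------------------------------
# 4PL model
# ---------------------------------------------------------------------------


def test_four_pl_midpoint_and_asymptotes():
    log_ic50 = math.log10(0.4)
    assert four_pl(0.4, 0, 100, 1, log_ic50) == pytest.approx(50.0)
    assert four_pl(1e-9, 0, 100, 1, log_ic50) == pytest.approx(100.0, abs=1e-4)
    assert four_pl(1e9, 0, 100, 1, log_ic50) == pytest.approx(0.0, abs=1e-4)


def test_four_pl_direct_value():
    # c = 5x IC50 with unit slope: survival 100 / 6
    assert four_pl(2.0, 0, 100, 1, math.log10(0.4)) == pytest.approx(100 / 6)


def test_four_pl_rejects_non_positive_dose():
    with pytest.raises(DoseResponseError):
        four_pl(0.0, 0, 100, 1, 0.0)


def test_four_pl_strictly_decreasing_for_positive_slope():
    doses = np.logspace(-3, 2, 40)
    for hill in (0.5, 1.0, 3.0):
        y = four_pl(doses, 5, 100, hill, math.log10(0.3))
        assert np.all(np.diff(y) < 0)


# ---------------------------------------------------------------------------
# Screen averaging
# ---------------------------------------------------------------------------


def test_average_screens_weights_screens_equally():
    # screen 2's duplicates average first: (80 + 65) / 2 = 72.5
    out = average_screens([80.0], [[60.0], [70.0]])
    assert out == pytest.approx([72.5])


def test_average_of_identical_screens_is_identity():
    resp = [90.0, 70.0, 40.0, 20.0, 10.0]
    np.testing.assert_allclose(average_screens(resp, resp), resp)


def test_mismatched_dose_grids_raise():
    with pytest.raises(DoseResponseError, match="mismatched"):
        average_screens([1.0, 2.0], [1.0, 2.0, 3.0])
    with pytest.raises(DoseResponseError, match="mismatched"):
        average_screens([1.0, 2.0], [1.0, 2.0], [10.0, 2.0], [10.0, 5.0])


# ---------------------------------------------------------------------------
# Fitting and adjudication
# ---------------------------------------------------------------------------


def test_noise_free_fit_recovers_the_generator():
    truth = (0.0, 100.0, 1.0, math.log10(0.4))
    responses = four_pl(np.array(DOSES), *truth)
    fit = fit_4pl(_series(responses))
    assert fit.status == "converged"
    assert fit.ic50_uM == pytest.approx(0.4, rel=1e-6)
    assert fit.hill == pytest.approx(1.0, rel=1e-6)
    assert fit.top == pytest.approx(100.0, rel=1e-6)
    assert abs(fit.bottom) < 1e-4


def test_flat_series_is_not_determinable():
    fit = fit_4pl(_series([100.0] * 5))
    assert fit.status == "nd"
    assert fit.ic50_display == "ND"
    assert "no dose dependence" in fit.message


def test_shallow_inhibition_is_above_range():
    # only 20% inhibition at the top dose -> IC50 beyond the range
    truth = (0.0, 100.0, 1.0, math.log10(50.0))
    responses = four_pl(np.array(DOSES), *truth)
    assert min(responses) > 70.0
    fit = fit_4pl(_series(responses))
    assert fit.status == "above_range"
    assert fit.ic50_display == ">10"


def test_potent_compound_is_flagged_extrapolated_but_numeric():
    truth = (0.0, 100.0, 1.0, math.log10(0.004))
    responses = four_pl(np.array(DOSES), *truth)
    fit = fit_4pl(_series(responses))
    assert fit.status == "extrapolated_low"
    assert fit.has_numeric_ic50
    assert fit.ic50_uM == pytest.approx(0.004, rel=1e-3)


def test_fit_invariant_to_dose_ordering():
    truth = (0.0, 100.0, 1.2, math.log10(0.3))
    responses = four_pl(np.array(DOSES), *truth)
    fit = fit_4pl(_series(responses))
    order = [3, 0, 4, 1, 2]
    shuffled = fit_4pl(
        DoseSeries("c", "1455", DOSES, tuple(responses)),
        doses=[DOSES[i] for i in order],
        responses=[responses[i] for i in order],
    )
    assert shuffled.ic50_uM == pytest.approx(fit.ic50_uM, rel=1e-9)
    assert shuffled.hill == pytest.approx(fit.hill, rel=1e-9)


def test_fit_scales_with_uniform_response_scaling():
    truth = (10.0, 100.0, 1.0, math.log10(0.3))
    responses = np.asarray(four_pl(np.array(DOSES), *truth))
    base = fit_4pl(_series(responses))
    scaled = fit_4pl(_series(0.5 * responses))
    assert scaled.ic50_uM == pytest.approx(base.ic50_uM, rel=1e-6)
    assert scaled.hill == pytest.approx(base.hill, rel=1e-6)
    assert scaled.top == pytest.approx(0.5 * base.top, rel=1e-6)
    assert scaled.bottom == pytest.approx(0.5 * base.bottom, rel=1e-4)


def test_fit_requires_four_dose_points():
    with pytest.raises(DoseResponseError):
        fit_4pl(_series([90.0, 50.0, 10.0], doses=DOSES[:3]))


def test_parameter_recovery_under_confirmation_noise():
    """Across a grid of potencies and slopes, the simulated two-screen
    design (singlet + duplicate, 8% multiplicative noise, equal-weight
    averaging) keeps the median relative IC50 error under 15% and almost
    never misclassifies a sub-µM compound as non-lead."""
    n_seeds = 200
    truths = [
        DoseResponseTruth(f"c{i}", "1455", 100.0, 0.0, math.log10(ic50), hill)
        for i, (ic50, hill) in enumerate(
            (i, h) for i in (0.02, 0.08, 0.4, 2.0) for h in (0.7, 1.0, 2.0)
        )
    ]
    true_ic50 = {t.compound_id: t.ic50_uM for t in truths}
    rel_errors = []
    misclassified = 0
    sub_micromolar_checks = 0
    for seed in range(1, n_seeds + 1):
        table = simulate_confirmation_screen(truths, GeneratorConfig(seed=seed))
        for fit in fit_confirmation_table(table):
            ic50 = true_ic50[fit.compound_id]
            if fit.has_numeric_ic50:
                rel_errors.append(abs(fit.ic50_uM - ic50) / ic50)
            if ic50 <= 1.0:
                sub_micromolar_checks += 1
                if not (fit.has_numeric_ic50 and fit.ic50_uM <= 1.0):
                    misclassified += 1
    assert np.median(rel_errors) < 0.15
    assert misclassified <= 0.05 * sub_micromolar_checks


# ---------------------------------------------------------------------------
# Lead triage
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "value, kind, number",
    [(0.37, "numeric", 0.37), ("0.02", "numeric", 0.02), ("ND", "nd", None),
     (">20", "above_range", None), (">10", "above_range", None)],
)
def test_parse_ic50_outcome(value, kind, number):
    k, n = parse_ic50_outcome(value)
    assert k == kind
    assert n == number


def test_reference_table_triage_counts():
    table = designate_leads(lead_ic50_outcomes())
    counts = categorize_leads(table)
    assert int(table["lead_any"].sum()) == 17
    assert counts == {"1455_only": 4, "1458_only": 6, "both": 7, "neither": 0}


def test_single_line_lead_assignment():
    outcomes = pd.DataFrame(
        {
            "compound_id": ["sild", "sild"],
            "cell_line": ["1455", "1458"],
            "ic50": [1.88, 0.96],
        }
    )
    table = designate_leads(outcomes)
    row = table.iloc[0]
    assert not row["lead_1455"] and row["lead_1458"]
    assert row["category"] == "1458_only"


def test_nd_and_above_range_never_lead():
    outcomes = pd.DataFrame(
        {
            "compound_id": ["a", "a", "b", "b"],
            "cell_line": ["1455", "1458"] * 2,
            "ic50": ["ND", "ND", ">0.5", ">0.5"],
        }
    )
    table = designate_leads(outcomes)
    assert not table["lead_any"].any()
    assert categorize_leads(table) == {
        "1455_only": 0, "1458_only": 0, "both": 0, "neither": 2
    }


def test_lead_cutoff_is_inclusive_at_one_micromolar():
    outcomes = pd.DataFrame(
        {"compound_id": ["x", "x"], "cell_line": ["1455", "1458"], "ic50": [1.0, 1.01]}
    )
    table = designate_leads(outcomes)
    assert table.iloc[0]["lead_1455"]
    assert not table.iloc[0]["lead_1458"]


def test_categories_partition_the_table():
    table = designate_leads(lead_ic50_outcomes())
    counts = categorize_leads(table)
    assert sum(counts.values()) == len(table)
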