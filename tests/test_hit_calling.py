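"""%E-DI statistic, adaptive threshold, hit calls, and screen summaries."""

import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from estroscreen.hit_calling import (
    HitCallingError,
    HitThreshold,
    ScreenSummary,
    call_hits,
    derive_threshold,
    edi,
    round_half_away,
    summarize_screen,
)
from estroscreen.normalize_filter import STATUS_RETAINED


@pytest.mark.parametrize(
    "alpha, beta, expected",
    [(1.0, 1.0, 0.0), (1.0, 0.25, 75.0), (0.9, 0.27, 70.0), (0.5, 0.0, 100.0)],
)
def test_edi_inhibition_form(alpha, beta, expected):
    assert edi(alpha, beta) == pytest.approx(expected)


def test_edi_as_printed_form_is_the_complement():
    assert edi(1.0, 0.25, form="as_printed") == pytest.approx(25.0)


@given(
    alpha=st.floats(min_value=0.01, max_value=5.0),
    beta=st.floats(min_value=0.0, max_value=5.0),
)
@settings(deadline=None)
def test_edi_forms_sum_to_one_hundred(alpha, beta):
    total = edi(alpha, beta, "inhibition") + edi(alpha, beta, "as_printed")
    assert total == pytest.approx(100.0, abs=1e-9)


@given(alpha=st.floats(min_value=0.01, max_value=5.0))
@settings(deadline=None)
def test_edi_fixed_points(alpha):
    assert edi(alpha, alpha) == pytest.approx(0.0, abs=1e-9)
    assert edi(alpha, 0.0) == pytest.approx(100.0)


def test_edi_strictly_decreasing_in_beta():
    values = [edi(1.0, b) for b in (0.0, 0.3, 0.6, 1.0, 1.5)]
    assert all(a > b for a, b in zip(values, values[1:]))


def test_edi_rejects_zero_alpha_and_negative_beta():
    with pytest.raises(HitCallingError, match="alpha"):
        edi(0.0, 0.5)
    with pytest.raises(HitCallingError, match="beta"):
        edi(1.0, -0.1)


# ---------------------------------------------------------------------------
# Threshold derivation
# ---------------------------------------------------------------------------


def test_threshold_mean_plus_two_and_a_half_sd():
    # mean 5, sample sd 26
    t = derive_threshold([-21.0, 5.0, 31.0])
    assert t.mean_edi == pytest.approx(5.0)
    assert t.sd_edi == pytest.approx(26.0)
    assert t.derived == pytest.approx(70.0)
    assert t.applied == pytest.approx(70.0)


def test_threshold_degenerate_all_zero():
    t = derive_threshold([0.0, 0.0, 0.0])
    assert t.derived == 0.0


def test_threshold_matches_independent_second_pass():
    rng = np.random.default_rng(12)
    values = rng.normal(5, 12, 500)
    t = derive_threshold(values)
    oracle = statistics.mean(values) + 2.5 * statistics.stdev(values)
    assert t.derived == pytest.approx(oracle, rel=1e-12)


def test_threshold_override_is_recorded_not_destructive():
    t = derive_threshold([-21.0, 5.0, 31.0], override=70.0)
    assert t.derived == pytest.approx(70.0)
    assert t.applied == 70.0
    assert t.override == 70.0


def test_threshold_needs_two_values():
    with pytest.raises(HitCallingError):
        derive_threshold([5.0])


# ---------------------------------------------------------------------------
# Hit calling
# ---------------------------------------------------------------------------


def _table(edis):
    df = pd.DataFrame(
        {
            "compound_id": [f"c{i}" for i in range(len(edis))],
            "cell_line": ["1455"] * len(edis),
            "alpha": 1.0,
            "beta": 1.0,
            "status": STATUS_RETAINED,
            "edi": edis,
        }
    )
    df.attrs["edi_form"] = "inhibition"
    return df


def test_hit_rule_is_strictly_above_threshold():
    threshold = HitThreshold(mean_edi=0, sd_edi=0, multiplier=2.5, override=70.0)
    out = call_hits(_table([70.0, 70.1, 69.9]), threshold)
    assert list(out["is_hit"]) == [False, True, False]


def test_unevaluable_rows_are_never_hits():
    threshold = HitThreshold(0, 0, 2.5, override=10.0)
    table = _table([50.0, np.nan])
    out = call_hits(table, threshold)
    assert list(out["is_hit"]) == [True, False]


def test_hit_sets_are_monotone_in_the_threshold():
    rng = np.random.default_rng(3)
    table = _table(list(rng.normal(10, 30, 200)))
    previous = None
    for cutoff in (0.0, 20.0, 40.0, 60.0, 80.0):
        hits = set(
            call_hits(table, HitThreshold(0, 0, 2.5, override=cutoff))
            .loc[lambda d: d["is_hit"], "compound_id"]
        )
        if previous is not None:
            assert hits <= previous
        previous = hits


# ---------------------------------------------------------------------------
# Summary arithmetic
# ---------------------------------------------------------------------------


def test_round_half_away():
    assert round_half_away(8.05) == 8.1
    assert round_half_away(8.04) == 8.0
    assert round_half_away(-8.05) == -8.1
    assert round_half_away(1.7006, 1) == 1.7


def _summary(n_library, n_excluded, hits_per_line, n_hits):
    return ScreenSummary(
        n_library=n_library,
        n_excluded_toxicity=n_excluded,
        n_analyzed=n_library - n_excluded,
        n_unevaluable=0,
        hits_per_line=hits_per_line,
        n_hits_total=n_hits,
        edi_form="inhibition",
        threshold=HitThreshold(5, 26, 2.5),
    )


def test_zero_removed_is_zero_percent():
    assert _summary(100, 0, {"1455": 0}, 0).pct_excluded == 0.0


def test_union_hit_counting():
    table = pd.DataFrame(
        {
            "compound_id": ["A", "B", "B", "C"],
            "cell_line": ["1455", "1455", "1458", "1458"],
            "alpha": 1.0,
            "beta": 0.1,
            "status": STATUS_RETAINED,
            "edi": [90.0] * 4,
        }
    )
    table.attrs["edi_form"] = "inhibition"
    out = call_hits(table, HitThreshold(0, 0, 2.5, override=70.0))
    summary = summarize_screen(out, HitThreshold(0, 0, 2.5, override=70.0))
    assert summary.hits_per_line == {"1455": 2, "1458": 2}
    assert summary.n_hits_total == 3  # union of {A, B} and {B, C}


def test_headline_percentages_recomputed_to_one_decimal():
    summary = _summary(3517, 283, {"1455": 19, "1458": 36}, 55)
    # recomputation gives 8.0/92.0, not the truncated 8.1/91.9 sometimes quoted
    assert summary.pct_excluded == 8.0
    assert summary.pct_analyzed == 92.0
    assert summary.pct_hits == pytest.approx(1.7)


def test_end_to_end_hit_calls_recover_programmed_effects_on_noise_free_screen(
    noise_free_config,
):
    """With noise off, measured %E-DI equals the programmed %E-DI up to the
    count-rounding quantum, so the hit set is exactly the set of non-toxic
    compounds whose programmed %E-DI exceeds the derived threshold (rows
    within the rounding band of the threshold are the only permissible
    discrepancies)."""
    from estroscreen.pipeline import PipelineConfig, run_primary

    result = run_primary(PipelineConfig(generator=noise_free_config))
    truth = result.dataset.truth
    merged = result.hit_table.merge(
        truth, on=["compound_id", "cell_line"], suffixes=("", "_truth")
    )
    cutoff = result.threshold.applied
    expected = (merged["true_edi"] > cutoff) & ~merged["is_toxic"]
    disagree = merged[merged["is_hit"] != expected]
    assert (abs(disagree["true_edi"] - cutoff) < 0.5).all()
    # and every programmed strong hit well clear of the threshold is called
    clear = merged[(merged["true_edi"] > cutoff + 0.5) & ~merged["is_toxic"]]
    assert clear["is_hit"].all()
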