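"""Field-evaluation arithmetic: reductions, product savings, tank refills."""

import pytest

from citrusvol import (
    ApplicationRecord,
    Ingredient,
    ValidationError,
    application_records,
    load_fixture,
    mix_reduction,
    ppp_savings,
    refill_time_savings,
    summarize_trials,
    tanks_needed,
)


@pytest.mark.parametrize(
    "vc, va, expected",
    [(6702, 1737, 74.08), (7311, 3011, 58.82), (1000, 1000, 0.0)],
)
def test_mix_reduction(vc, va, expected):
    assert mix_reduction(vc, va) == pytest.approx(expected, abs=0.005)


def test_mix_reduction_flags_inverted_rates():
    with pytest.raises(ValidationError):
        mix_reduction(1000, 1200)


@pytest.mark.parametrize(
    "conc, vc, va, expected",
    [(0.20, 6702, 1737, 9.93), (0.04, 7311, 3011, 1.72), (0.20, 4905, 3255, 3.30)],
)
def test_ppp_savings(conc, vc, va, expected):
    assert ppp_savings(conc, vc, va) == pytest.approx(expected, abs=0.005)


@pytest.mark.parametrize(
    "rate, area, cap, expected",
    [(7311, 1, 2000, 4), (3011, 1, 2000, 2), (2000, 1, 2000, 1)],
)
def test_tanks_needed(rate, area, cap, expected):
    assert tanks_needed(rate, area, cap) == expected


def test_tanks_needed_whole_area_equivalence():
    """ceil over the whole area equals folding the area into the rate."""
    for rate, area, cap in [(4905, 10, 1500), (3318, 100, 3000), (3215, 7, 1500)]:
        assert tanks_needed(rate, area, cap) == tanks_needed(rate * area, 1, cap)


@pytest.mark.parametrize(
    "vc, va, cap, area, expected",
    [
        (7311, 3011, 2000, 1, 1.33),
        (4905, 3255, 1500, 100, 73.33),
        (3468, 3065, 3000, 1, 0.0),
    ],
)
def test_refill_time_savings(vc, va, cap, area, expected):
    assert refill_time_savings(vc, va, cap, area) == pytest.approx(expected, abs=0.005)


def test_refill_savings_nondecreasing_in_area():
    prev = 0.0
    for area in (1, 2, 5, 10, 20, 50, 100):
        cur = refill_time_savings(4905, 3255, 1500, area)
        assert cur >= prev
        prev = cur


def test_all_printed_refill_cells_reproduced():
    """Every published time-savings cell follows from the whole-area ceiling
    convention at 40 min per tank (±0.02 h print rounding)."""
    t6 = load_fixture("T6")
    rates = {
        (r.orchard_id, r.date): (r.vc, r.va)
        for r in load_fixture("T5").itertuples()
    }
    # T5 prints 13 June for P6's first application where T6 prints 16 June
    rates[("P6", "2016-06-16")] = rates.pop(("P6", "2016-06-13"))
    for r in t6.itertuples():
        vc, va = rates[(r.orchard_id, r.date)]
        assert tanks_needed(vc, 1, r.tank_capacity) == r.tanks_vc
        assert tanks_needed(va, 1, r.tank_capacity) == r.tanks_va
        for area, printed in [(1, r.savings_h_1ha), (10, r.savings_h_10ha),
                              (100, r.savings_h_100ha)]:
            computed = refill_time_savings(vc, va, r.tank_capacity, area)
            assert computed == pytest.approx(printed, abs=0.02), (
                r.orchard_id, r.date, area
            )


def test_application_record_validation():
    with pytest.raises(ValidationError):
        ApplicationRecord("P1", "2016-05-27", "CRS", vc=1000, va=2000,
                          tank_capacity=1500)
    with pytest.raises(ValidationError):
        Ingredient("chlorpyrifos", 0)


def test_summarize_trials_overall_stats():
    summary = summarize_trials(application_records())
    assert len(summary.applications) == 14
    assert summary.min_reduction_pct == pytest.approx(11.61, abs=0.02)
    assert summary.max_reduction_pct == pytest.approx(74.08, abs=0.005)
    # recomputed mean exceeds the published 31.5% because two printed
    # reduction cells disagree with their own volume rates (see below)
    assert summary.mean_reduction_pct == pytest.approx(33.66, abs=0.01)


def test_summarize_trials_small_cases():
    rec = ApplicationRecord("X", "d", "p", vc=1000, va=800, tank_capacity=1500)
    assert summarize_trials([rec]).mean_reduction_pct == pytest.approx(20.0)
    two = [
        ApplicationRecord("X", "d", "p", vc=1000, va=800, tank_capacity=1500),
        ApplicationRecord("Y", "d", "p", vc=1000, va=600, tank_capacity=1500),
    ]
    assert summarize_trials(two).mean_reduction_pct == pytest.approx(30.0)
    with pytest.raises(ValidationError):
        summarize_trials([])


def test_published_reduction_column_mean_is_31_5():
    """The published mean (31.5%) is the unweighted mean of the printed
    per-application reduction column."""
    t5 = load_fixture("T5").drop_duplicates(["orchard_id", "date"])
    assert len(t5) == 14
    assert t5["reduction_printed"].mean() == pytest.approx(31.5, abs=0.05)


def test_known_typo_rows_flagged_as_discrepancies():
    """Two printed reduction cells do not match their own Vc/Va pairs; the
    fixture keeps the printed values and the recomputation disagrees."""
    t5 = load_fixture("T5").drop_duplicates(["orchard_id", "date"]).set_index(
        ["orchard_id", "date"]
    )
    p6 = t5.loc[("P6", "2016-08-12")]
    assert p6["reduction_printed"] == 20.81
    assert mix_reduction(p6["vc"], p6["va"]) == pytest.approx(50.93, abs=0.01)
    p2 = t5.loc[("P2", "2016-09-09")]
    assert p2["reduction_printed"] == 22.28
    assert mix_reduction(p2["vc"], p2["va"]) == pytest.approx(22.99, abs=0.01)
    # every other row agrees with its printed cell; several cells carry up
    # to 0.03 points of print rounding (e.g. 20.78 computed vs 20.81 printed)
    others = t5.drop([("P6", "2016-08-12"), ("P2", "2016-09-09")])
    for (orch, date), row in others.iterrows():
        assert mix_reduction(row["vc"], row["va"]) == pytest.approx(
            row["reduction_printed"], abs=0.03
        ), (orch, date)


def test_printed_savings_column_reproduced():
    """Published per-ingredient product savings follow from concentration
    × volume difference (±0.01 print rounding)."""
    for r in load_fixture("T5").itertuples():
        assert ppp_savings(r.concentration_pct, r.vc, r.va) == pytest.approx(
            r.savings_printed, abs=0.01
        ), (r.orchard_id, r.date, r.ingredient)
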