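"""Rate estimation, annualization and printed-matrix loading."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metsmarkov import (
    EstimationConfig,
    MetabolicState,
    PanelObservation,
    RateMatrix,
    TransitionCountTable,
    annualize_probability,
    build_transition_matrix,
    count_transitions,
    estimate_rates,
    load_fixture,
    load_printed_matrix,
    read_panel_csv,
    write_matrix_csv,
    write_panel_csv,
)
from metsmarkov.estimation import _read_matrix_percent_csv

A = MetabolicState.NO_COMPONENT
B = MetabolicState.METS


def obs(i, t0, t1, sex="male", years=5.0):
    return PanelObservation(f"s{i}", sex, t0, t1, years)


class TestCountTransitions:
    def test_direct_tally_and_person_years(self):
        panel = [obs(0, A, B), obs(1, A, B), obs(2, A, B), obs(3, A, A)]
        t = count_transitions(panel)
        assert t.counts[int(A), int(B)] == 3
        assert t.counts[int(A), int(A)] == 1
        assert t.person_years[int(A)] == pytest.approx(20.0)
        assert t.origin_totals[int(A)] == 4
        assert t.counts.sum() == 4

    def test_empty_panel_warns_and_returns_zero_table(self):
        with pytest.warns(UserWarning, match="empty panel"):
            t = count_transitions([])
        assert t.counts.sum() == 0 and t.person_years.sum() == 0

    def test_mixed_sexes_rejected(self):
        panel = [obs(0, A, B, sex="male"), obs(1, A, B, sex="female")]
        with pytest.raises(ValueError, match="mixes sex strata"):
            count_transitions(panel)


class TestEstimateRates:
    def test_rate_is_events_over_person_years(self):
        counts = np.zeros((8, 8), dtype=int)
        counts[0, 7] = 3
        py = np.zeros(8)
        py[0] = 150.0
        rm = estimate_rates(TransitionCountTable(counts, py))
        assert rm.rates[0, 7] == pytest.approx(0.02)
        assert rm.rates[0, 1] == 0.0  # zero events -> rate 0

    def test_events_without_person_time_rejected(self):
        counts = np.zeros((8, 8), dtype=int)
        counts[0, 7] = 3
        with pytest.raises(ValueError, match="zero person-time"):
            estimate_rates(TransitionCountTable(counts, np.zeros(8)))

    def test_zero_person_year_rows_warn(self):
        counts = np.zeros((8, 8), dtype=int)
        counts[0, 7] = 1
        py = np.zeros(8)
        py[0] = 10.0
        with pytest.warns(UserWarning, match="zero person-years"):
            rm = estimate_rates(TransitionCountTable(counts, py))
        assert np.all(rm.rates[1:] == 0)

    def test_continuity_correction_fills_zero_cells(self):
        counts = np.zeros((8, 8), dtype=int)
        counts[0, 7] = 3
        py = np.zeros(8)
        py[0] = 150.0
        rm = estimate_rates(
            TransitionCountTable(counts, py),
            EstimationConfig(continuity_correction=True),
        )
        assert rm.rates[0, 1] == pytest.approx(0.5 / 150.0)
        assert rm.rates[0, 7] == pytest.approx(0.02)  # observed cells untouched
        assert np.all(rm.rates[1:] == 0)  # rows without person-time untouched


class TestAnnualize:
    def test_closed_form_values(self):
        assert annualize_probability(0.0, 7.3) == 0.0
        # the published aggregate MetS incidence in men, 19.5/1000 py
        assert annualize_probability(0.0195, 1.0) == pytest.approx(
            0.019311, abs=5e-7
        )
        assert annualize_probability(30.0, 1.0) == pytest.approx(1.0, abs=1e-12)
        assert annualize_probability(30.0, 1.0) < 1.0

    def test_negative_rate_and_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            annualize_probability(-0.1, 1.0)
        with pytest.raises(ValueError):
            annualize_probability(0.1, 0.0)

    @given(r=st.floats(1e-6, 3), t1=st.floats(0.1, 5), t2=st.floats(0.1, 5),
           dr=st.floats(1e-6, 1))
    @settings(max_examples=200, deadline=None)
    def test_strictly_increasing_in_rate_and_time(self, r, t1, t2, dr):
        p = annualize_probability(r, t1)
        assert 0 < p < 1
        assert annualize_probability(r + dr, t1) > p
        assert annualize_probability(r, t1 + t2) > p
        # exact composition: 1 - exp(-r(t1+t2))
        assert annualize_probability(r, t1 + t2) == pytest.approx(
            1 - (1 - p) * (1 - annualize_probability(r, t2)), rel=1e-9
        )


class TestBuildTransitionMatrix:
    def test_zero_rates_give_identity(self):
        tm = build_transition_matrix(RateMatrix(np.zeros((8, 8))))
        assert np.array_equal(tm.probs, np.eye(8))

    def test_rows_sum_to_one_exactly(self):
        rng = np.random.default_rng(7)
        rates = rng.uniform(0, 0.05, (8, 8))
        tm = build_transition_matrix(RateMatrix(rates))
        assert np.allclose(tm.probs.sum(axis=1), 1.0, atol=1e-12)
        off = tm.probs[~np.eye(8, dtype=bool)]
        expected = -np.expm1(-rates[~np.eye(8, dtype=bool)])
        assert np.allclose(off, expected, atol=1e-15)

    def test_oversized_rates_rejected_with_row_named(self):
        rates = np.zeros((8, 8))
        rates[3, :] = 2.0  # seven off-diagonal cells each annualize to ~0.86
        with pytest.raises(ValueError, match="ISO_LOW_HDL"):
            build_transition_matrix(RateMatrix(rates))


class TestPrintedMatrix:
    def test_fixture_rows_renormalized_onto_simplex(self, men_matrix):
        assert np.allclose(men_matrix.probs.sum(axis=1), 1.0, atol=1e-12)
        # the published men's no-component row sums to 99.99 before renormalizing
        raw = _raw_fixture_percent("men_table2")
        assert raw[0].sum() == pytest.approx(99.99, abs=1e-9)

    def test_roundtrip_reproduces_printed_percentages(self, women_matrix):
        """Undoing the renormalization recovers the printed table to 0.01."""
        raw = _raw_fixture_percent("women_table3")
        row_sums = raw.sum(axis=1)
        recovered = women_matrix.probs * row_sums[:, None]
        assert np.allclose(recovered, raw, atol=0.01)

    def test_normalized_row_passes_through_unchanged(self):
        percent = np.full((8, 8), 12.5)
        tm = load_printed_matrix(percent)
        assert np.allclose(tm.probs, 0.125, atol=1e-15)

    def test_bad_row_sum_rejected_naming_the_row(self):
        percent = np.full((8, 8), 12.5)
        percent[5, 5] = 20.0  # row now sums to 107.5
        with pytest.raises(ValueError, match="ISO_HIGH_FPG"):
            load_printed_matrix(percent)

    def test_matrix_csv_roundtrip(self, men_matrix, tmp_path):
        path = tmp_path / "m.csv"
        write_matrix_csv(men_matrix, path)
        assert np.allclose(
            _read_matrix_percent_csv(path), men_matrix.probs * 100, atol=1e-6
        )


def test_panel_csv_roundtrip(tmp_path):
    panel = [obs(0, A, B), obs(1, B, A, years=4.5)]
    path = tmp_path / "panel.csv"
    write_panel_csv(panel, path)
    back = read_panel_csv(path)
    assert back == panel


def _raw_fixture_percent(name):
    from importlib import resources

    ref = resources.files("metsmarkov.data").joinpath(f"{name}.csv")
    with ref.open() as fh:
        return _read_matrix_percent_csv(fh)
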