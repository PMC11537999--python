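"""Curve classification, rank mapping, and activity-outcome logic."""

import itertools

import numpy as np
import pandas as pd
import pytest

from qhts.classify import (
    activity_outcome,
    assign_class,
    call_compound,
    confirmation_rate,
    curve_rank,
    select_confirmation,
    select_followup,
)
from qhts.hillfit import ConcentrationResponse, HillFit, fit_hill, hill_eval
from qhts.synthetic import ScreenConfig, plate_concentrations

CONCS = plate_concentrations(ScreenConfig())
ALL_CLASSES = [s * c for c in (1.1, 1.2, 2.1, 2.2, 3.0) for s in (1, -1)] + [4.0]


def series(resp):
    return ConcentrationResponse(compound_id="X", concentration=CONCS, response=np.asarray(resp, dtype=float))


class TestAssignClass:
    def test_all_points_in_noise_band_is_class4(self):
        cr = series(np.full(7, 2.0))
        assert assign_class(fit_hill(cr), cr, noise_band=10.0) == 4.0

    def test_complete_inhibition_sigmoid_is_class_neg_1_1(self):
        truth = HillFit(a0=0, a_inf=-100, k=0.1, n=2.0, r_squared=1.0, converged=True)
        cr = series(hill_eval(truth, CONCS))
        fit = fit_hill(cr)
        assert fit.r_squared > 0.99
        assert assign_class(fit, cr, noise_band=10.0) == -1.1

    def test_single_active_point_is_class3(self):
        resp = np.zeros(7)
        resp[-1] = -60.0
        cr = series(resp)
        assert assign_class(fit_hill(cr), cr, noise_band=10.0) == -3.0

    def test_incomplete_curve_is_class2(self):
        # potency near the top of the series: lower asymptote only
        truth = HillFit(a0=0, a_inf=-100, k=30.0, n=1.5, r_squared=1.0, converged=True)
        cr = series(hill_eval(truth, CONCS))
        cls = assign_class(fit_hill(cr), cr, noise_band=10.0)
        assert abs(cls) in (2.1, 2.2)
        assert cls < 0

    def test_weak_efficacy_gets_subclass_2(self):
        truth = HillFit(a0=0, a_inf=-60, k=0.1, n=2.0, r_squared=1.0, converged=True)
        cr = series(hill_eval(truth, CONCS))
        assert assign_class(fit_hill(cr), cr, noise_band=10.0) == -1.2

    def test_activation_curve_gets_positive_sign(self):
        truth = HillFit(a0=0, a_inf=100, k=0.1, n=2.0, r_squared=1.0, converged=True)
        cr = series(hill_eval(truth, CONCS))
        assert assign_class(fit_hill(cr), cr, noise_band=10.0) == 1.1


class TestCurveRank:
    @pytest.mark.parametrize(
        "cls,eff,expected",
        [
            (4.0, -100.0, 0),
            (-1.1, -100.0, -9),
            (-1.1, -60.0, -8),
            (-3.0, -55.0, -1),
            (-2.2, -85.0, -3),
            (1.1, 95.0, 9),
            (2.1, 50.0, 4),
        ],
    )
    def test_mapping_table(self, cls, eff, expected):
        assert curve_rank(cls, eff) == expected

    def test_exhaustive_bounds_and_class4_zero(self):
        """Ranks live in [-9, 9]; 0 iff class 4; +/-9 only for class +/-1.1."""
        for cls, eff in itertools.product(ALL_CLASSES, np.arange(-100, 101, 1.0)):
            r = curve_rank(cls, eff)
            assert -9 <= r <= 9
            assert (r == 0) == (cls == 4.0)
            if abs(r) == 9:
                assert abs(cls) == 1.1
            if cls != 4.0:
                assert np.sign(r) == np.sign(cls)

    def test_monotone_in_efficacy_within_class(self):
        for cls in ALL_CLASSES:
            mags = [abs(curve_rank(cls, e)) for e in np.arange(0, 101, 5.0)]
            assert all(b >= a for a, b in zip(mags, mags[1:]))

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            curve_rank(-5.0, -50.0)


def oracle_outcome(rank, eff, viability_active, sep):
    """Brute-force restatement of the activity rule."""
    counter_ok = (not viability_active) or (sep is not None and sep >= 6.0)
    if rank < -1 and eff < -50.0 and counter_ok:
        return "active"
    if abs(rank) < 1:
        return "inactive"
    return "inconclusive"


class TestActivityOutcome:
    @pytest.mark.parametrize(
        "rank,eff,viab,sep,expected",
        [
            (-5, -90.0, False, None, "active"),
            (0, 0.0, False, None, "inactive"),
            (-4, -80.0, True, 2.0, "inconclusive"),  # fails the 6-fold rescue
            (-4, -80.0, True, 6.0, "active"),  # exactly 6-fold rescues
            (-2, -51.0, False, None, "active"),
            (-1, -90.0, False, None, "inconclusive"),  # rank not < -1
            (3, 60.0, False, None, "inconclusive"),  # activator, not an antagonist call
        ],
    )
    def test_reference_cases(self, rank, eff, viab, sep, expected):
        assert activity_outcome(rank, eff, viab, sep) == expected

    def test_matches_truth_table_oracle(self):
        """Exhaustive sweep over every branch combination."""
        ranks = range(-9, 10)
        effs = [-120.0, -75.0, -50.0, -49.0, 0.0, 60.0]
        seps = [None, 0.5, 5.9, 6.0, 100.0]
        for rank, eff, viab, sep in itertools.product(ranks, effs, [False, True], seps):
            assert activity_outcome(rank, eff, viab, sep) == oracle_outcome(rank, eff, viab, sep)


def toy_calls():
    rows = [
        # id, efficacy, ic50, viability class, separation
        ("A", -80.0, 1.0, 4.0, None),  # clean potent hit
        ("B", -40.0, 1.0, 4.0, None),  # too weak
        ("C", -90.0, 20.0, 4.0, None),  # too impotent
        ("D", -85.0, 0.5, -1.1, 2.0),  # cytotoxic, poor separation
        ("E", -85.0, 0.5, -1.1, 8.0),  # cytotoxic but 8-fold separated
        ("F", -60.0, 5.0, 4.0, None),  # confirmation-only (fails E<-75)
        ("G", -76.0, 9.9, 4.0, None),  # boundary follow-up pass
        ("H", -75.0, 1.0, 4.0, None),  # boundary follow-up fail (strict)
        ("I", -100.0, 0.01, -2.1, 5.99),  # just under 6-fold
        ("J", -55.0, 10.0, 4.0, None),  # boundary potency fail (strict)
    ]
    return pd.DataFrame(
        rows, columns=["compound_id", "efficacy", "ic50_um", "viability_class", "potency_separation"]
    )


class TestSelection:
    def test_confirmation_filter_matches_row_oracle(self):
        calls = toy_calls()
        expected = [
            r.compound_id
            for r in calls.itertuples()
            if r.efficacy < -50
            and r.ic50_um < 10
            and (abs(r.viability_class) == 4.0 or (r.potency_separation or 0) >= 6)
        ]
        assert select_confirmation(calls) == expected == ["A", "E", "F", "G", "H"]

    def test_followup_uses_tighter_efficacy(self):
        assert select_followup(toy_calls()) == ["A", "E", "G"]

    def test_negative_controls_appended(self):
        assert select_confirmation(toy_calls(), extra_ids=["NEG1"])[-1] == "NEG1"


class TestConfirmationRate:
    @pytest.mark.parametrize("p,c,expected", [(94, 66, 70.2), (10, 10, 100.0), (10, 3, 30.0)])
    def test_values(self, p, c, expected):
        assert confirmation_rate(p, c) == expected

    def test_validation(self):
        with pytest.raises(ValueError):
            confirmation_rate(0, 0)
        with pytest.raises(ValueError):
            confirmation_rate(5, 6)


class TestCallCompound:
    def test_cytotoxic_compound_is_not_called_active(self):
        """Luminescence loss that tracks viability loss is flagged, not called."""
        act = series_pair(ic50_act=1.0, ic50_via=1.0)
        call = call_compound(act[0], act[1], noise_band=10.0)
        assert call.outcome == "inconclusive"
        assert call.potency_separation == pytest.approx(1.0, rel=0.2)

    def test_selective_antagonist_called_active(self):
        act = series_pair(ic50_act=0.2, ic50_via=None)
        call = call_compound(act[0], act[1], noise_band=10.0)
        assert call.outcome == "active"
        assert call.curve_rank <= -2


def series_pair(ic50_act, ic50_via):
    act_fit = HillFit(a0=0, a_inf=-95, k=ic50_act, n=1.5, r_squared=1, converged=True)
    act = ConcentrationResponse("X", CONCS, hill_eval(act_fit, CONCS), readout="activity")
    if ic50_via is None:
        via = ConcentrationResponse("X", CONCS, np.zeros(len(CONCS)), readout="viability")
    else:
        via_fit = HillFit(a0=0, a_inf=-95, k=ic50_via, n=1.5, r_squared=1, converged=True)
        via = ConcentrationResponse("X", CONCS, hill_eval(via_fit, CONCS), readout="viability")
    return act, via
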