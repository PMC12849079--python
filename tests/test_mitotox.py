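import numpy as np
import pytest

from conftest import make_run, meta, plateau_trace
from nerveflux.mitotox import (
    DegenerateReferenceError,
    ReferenceLine,
    ReferenceSummary,
    build_reference_line,
    compute_mti_f,
    compute_mti_u,
    compute_zscores,
    toxicity_table,
)
from nerveflux.plate_model import Trace


def posneg_run():
    """Two positive animals with distinct levels plus two negative controls."""
    wells = [
        (meta("P1", "a1", "ctrl", status="pass"), plateau_trace(28, 13, 65, 9)),
        (meta("P2", "a2", "ctrl", status="pass"), plateau_trace(32, 15, 75, 11)),
        (meta("N1", "a1", "ctrl", negative=True, status="exempt"), plateau_trace(9, 9, 9, 9)),
        (meta("N2", "a2", "ctrl", negative=True, status="exempt"), plateau_trace(11, 11, 11, 11)),
    ]
    return make_run(wells)


def manual_reference(kind="positive", **summary) -> ReferenceLine:
    defaults = dict(
        last_basal_mean=11.2,
        last_basal_sd=1.1,
        min_omy=14.0,
        max_fccp=60.0,
        min_fccp_window=5.0,
        max_fccp_mean=60.0,
        max_fccp_sd=2.0,
    )
    defaults.update(summary)
    sched = plateau_trace(30, 14, 70, 10).schedule
    return ReferenceLine(
        mean_ocr=np.zeros(sched.n_total),
        sd_ocr=np.zeros(sched.n_total),
        n_wells=2,
        member_wells=("x", "y"),
        kind=kind,
        schedule=sched,
        summary=ReferenceSummary(**defaults),
    )


class TestBuildReferenceLine:
    def test_identical_members_mean_is_member(self):
        t = plateau_trace(30, 14, 70, 10)
        run = make_run(
            [
                (meta("W1", "a1", "ctrl", status="pass"), t),
                (meta("W2", "a2", "ctrl", status="pass"), plateau_trace(30, 14, 70, 10)),
            ]
        )
        line = build_reference_line(run, group="ctrl")
        np.testing.assert_allclose(line.mean_ocr, t.ocr)
        np.testing.assert_allclose(line.sd_ocr, 0.0)

    def test_single_member_is_itself(self):
        t = plateau_trace(30, 14, 70, 10)
        run = make_run([(meta("W1", status="pass", group="g"), t)])
        line = build_reference_line(run, group="g")
        np.testing.assert_allclose(line.mean_ocr, t.ocr)
        assert line.n_wells == 1

    def test_pointwise_average(self):
        run = make_run(
            [
                (meta("W1", "a1", "g", status="pass"), plateau_trace(10, 10, 10, 10)),
                (meta("W2", "a2", "g", status="pass"), plateau_trace(30, 30, 30, 30)),
            ]
        )
        line = build_reference_line(run, group="g")
        np.testing.assert_allclose(line.mean_ocr, 20.0)

    def test_negative_selector_uses_pretreated_wells(self):
        line = build_reference_line(posneg_run(), negative=True)
        assert set(line.member_wells) == {"N1", "N2"}
        assert line.summary.min_fccp_window == pytest.approx(10.0)  # mean of 9 and 11

    def test_positive_excludes_negative_controls(self):
        line = build_reference_line(posneg_run(), group="ctrl")
        assert set(line.member_wells) == {"P1", "P2"}
        assert line.summary.last_basal_mean == pytest.approx(30.0)
        assert line.summary.last_basal_sd == pytest.approx(np.std([28, 32], ddof=1))

    def test_empty_selection_raises(self):
        with pytest.raises(DegenerateReferenceError):
            build_reference_line(posneg_run(), group="nothere")

    def test_members_with_missing_readings_dropped(self):
        run = posneg_run()
        run.wells["P1"].trace.ocr[3] = np.nan
        line = build_reference_line(run, group="ctrl")
        assert line.member_wells == ("P2",)


class TestScores:
    def test_mti_f_anchors(self):
        pos = manual_reference()
        neg = manual_reference(kind="negative")
        at_pos = plateau_trace(30, 14, 60, 10)  # test max_fccp == pos max_fccp
        assert compute_mti_f(at_pos, pos, neg) == pytest.approx(0.0)
        at_floor = plateau_trace(30, 4, 5, 4)  # test max_fccp == neg fccp-window min
        assert compute_mti_f(at_floor, pos, neg) == pytest.approx(-1.0)

    def test_mti_f_arithmetic(self):
        pos, neg = manual_reference(), manual_reference(kind="negative")
        test = plateau_trace(30, 14, 38.5, 10)
        assert compute_mti_f(test, pos, neg) == pytest.approx((38.5 - 60) / 55)

    def test_mti_u_anchors_and_arithmetic(self):
        pos = manual_reference()
        coupled = plateau_trace(30, 14, 70, 10)  # last-6 Omy max == pos min_omy
        assert compute_mti_u(coupled, pos) == pytest.approx(0.0)
        uncoupled = plateau_trace(70, 60, 70, 10)  # last-6 Omy max == pos max_fccp
        assert compute_mti_u(uncoupled, pos) == pytest.approx(1.0)
        test = plateau_trace(30, 25.2, 70, 10)
        assert compute_mti_u(test, pos) == pytest.approx(11.2 / 46)

    def test_zscore_anchors_and_arithmetic(self):
        pos = manual_reference()
        at_mean = plateau_trace(11.2, 5, 60, 4)
        z_b, z_f = compute_zscores(at_mean, pos)
        assert z_b == pytest.approx(0.0)
        assert z_f == pytest.approx(0.0)
        one_sd_up = plateau_trace(11.2 + 1.1, 5, 62, 4)
        z_b, z_f = compute_zscores(one_sd_up, pos)
        assert z_b == pytest.approx(1.0)
        assert z_f == pytest.approx(1.0)
        low = plateau_trace(9.0, 5, 60, 4)
        assert compute_zscores(low, pos)[0] == pytest.approx(-2.0)

    def test_member_mean_zscore_is_zero(self):
        run = posneg_run()
        pos = build_reference_line(run, group="ctrl")
        zs = [compute_zscores(run.wells[w].trace, pos) for w in ("P1", "P2")]
        assert np.mean([z[0] for z in zs]) == pytest.approx(0.0, abs=1e-12)
        assert np.mean([z[1] for z in zs]) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_test_statistic(self):
        pos, neg = manual_reference(), manual_reference(kind="negative")
        vals = [compute_mti_f(plateau_trace(30, 14, f, 10), pos, neg) for f in (20, 40, 60)]
        assert vals == sorted(vals)
        vals_u = [compute_mti_u(plateau_trace(30, o, 70, 10), pos) for o in (10, 20, 30)]
        assert vals_u == sorted(vals_u)

    def test_degenerate_denominators_raise(self):
        flat_pos = manual_reference(max_fccp=5.0)  # pos max below neg min
        with pytest.raises(DegenerateReferenceError):
            compute_mti_f(plateau_trace(30, 14, 70, 10), flat_pos, manual_reference())
        coupled_pos = manual_reference(min_omy=60.0)
        with pytest.raises(DegenerateReferenceError):
            compute_mti_u(plateau_trace(30, 14, 70, 10), coupled_pos)
        no_spread = manual_reference(last_basal_sd=0.0)
        with pytest.raises(DegenerateReferenceError):
            compute_zscores(plateau_trace(30, 14, 70, 10), no_spread)

    def test_common_rescaling_invariance(self):
        run = posneg_run()
        c = 1.7
        scaled = run.copy()
        for w in scaled.wells.values():
            w.trace.ocr *= c
        for r, s in [(run, scaled)]:
            pos_r = build_reference_line(r, group="ctrl")
            neg_r = build_reference_line(r, negative=True)
            pos_s = build_reference_line(s, group="ctrl")
            neg_s = build_reference_line(s, negative=True)
            test_r = plateau_trace(30, 14, 38.5, 10)
            test_s = Trace(test_r.ocr * c, test_r.ecar, test_r.schedule)
            assert compute_mti_f(test_s, pos_s, neg_s) == pytest.approx(
                compute_mti_f(test_r, pos_r, neg_r), rel=1e-12
            )
            assert compute_mti_u(test_s, pos_s) == pytest.approx(
                compute_mti_u(test_r, pos_r), rel=1e-12
            )
            np.testing.assert_allclose(
                compute_zscores(test_s, pos_s), compute_zscores(test_r, pos_r), rtol=1e-12
            )


class TestToxicityTable:
    def test_columns_and_rows(self):
        run = posneg_run()
        pos = build_reference_line(run, group="ctrl")
        neg = build_reference_line(run, negative=True)
        table = toxicity_table(run, pos, neg)
        assert set(table["well_id"]) == {"P1", "P2"}
        assert {"mti_f", "mti_u", "z_basal", "z_fccp"} <= set(table.columns)
        assert np.isfinite(table[["mti_f", "mti_u", "z_basal", "z_fccp"]]).all().all()
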