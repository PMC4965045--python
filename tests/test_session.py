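import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nirsbci import (
    HemoParams,
    ThermometerState,
    channel_tmap,
    crossvalidate_5fold,
    evaluate_roc,
    experiment_plan,
    extract_features,
    fit_model,
    generate_run,
    generate_subject,
    make_run_spec,
    run_experiment,
    run_online_session,
    step_thermometer,
)
from nirsbci.svm import LABEL_SIGN, decision_values, rest_bias


@pytest.fixture(scope="module")
def trained(layout, me_run):
    return fit_model([extract_features(me_run)], layout)


@pytest.fixture(scope="module")
def test_run(layout):
    spec = make_run_spec(task_type="ME", run_index=2, seed=21)
    return generate_run(spec, layout, HemoParams(), seed=21)


@pytest.fixture(scope="module")
def session(test_run, trained):
    selector, model = trained
    return run_online_session(test_run, selector, model)


class TestThermometer:
    def test_unit_rise(self):
        s = step_thermometer(ThermometerState(), correct=True, in_task=True, block_ended=False)
        assert s.grade == 1

    def test_unit_fall(self):
        s = step_thermometer(ThermometerState(grade=3), False, True, False)
        assert s.grade == 2

    def test_clamped_at_top(self):
        s = step_thermometer(ThermometerState(grade=10), True, True, False)
        assert s.grade == 10

    def test_clamped_at_bottom(self):
        s = step_thermometer(ThermometerState(grade=-10), False, True, False)
        assert s.grade == -10

    def test_block_end_resets(self):
        s = step_thermometer(ThermometerState(grade=7), True, True, True)
        assert s.grade == 0

    def test_rest_holds_zero(self):
        s = step_thermometer(ThermometerState(grade=5), True, False, False)
        assert s.grade == 0

    def test_dynamic_range_20_levels(self):
        s = ThermometerState()
        for _ in range(50):
            s = step_thermometer(s, True, True, False)
        top = s.grade
        for _ in range(50):
            s = step_thermometer(s, False, True, False)
        assert top - s.grade == 20

    @given(st.lists(st.booleans(), min_size=1, max_size=200))
    @settings(deadline=None)
    def test_grade_always_in_range(self, outcomes):
        s = ThermometerState()
        for ok in outcomes:
            s = step_thermometer(s, ok, True, False)
            assert -10 <= s.grade <= 10


class TestEvaluateRoc:
    def test_perfect_ordering(self):
        r = evaluate_roc([3.0, 2.0, -2.0, -3.0], [1, 1, -1, -1])
        assert r.auc == pytest.approx(1.0)

    def test_hand_enumerated_auc(self):
        # thresholds swept over [0.9, 0.8, 0.3, 0.1]: TPR/FPR staircase gives 0.75
        r = evaluate_roc([0.9, 0.8, 0.3, 0.1], [1, -1, 1, -1])
        assert r.auc == pytest.approx(0.75)

    def test_chance_level(self):
        rng = np.random.default_rng(0)
        r = evaluate_roc(rng.normal(size=1000), rng.choice([-1, 1], 1000))
        assert 0.45 <= r.auc <= 0.55

    def test_operating_point_at_zero_threshold(self):
        vals = np.array([1.0, -1.0, 2.0, -0.5])
        labs = np.array([1, 1, -1, -1])
        r = evaluate_roc(vals, labs)
        assert r.operating_point == (0.5, 0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            evaluate_roc([1.0, 2.0], [1, 1])

    def test_string_labels(self):
        r = evaluate_roc([1.0, -1.0], ["right", "left"])
        assert r.auc == pytest.approx(1.0)


class TestRunOnlineSession:
    def test_high_accuracy_on_clean_data(self, layout, quiet_params):
        train = generate_run(make_run_spec(run_index=1, seed=1), layout, quiet_params, seed=1)
        test = generate_run(make_run_spec(run_index=2, seed=2), layout, quiet_params, seed=2)
        sel, model = fit_model([extract_features(train)], layout)
        res = run_online_session(test, sel, model)
        assert res.accuracy_pct == pytest.approx(100.0)

    def test_accuracy_matches_confusion_of_traces(self, session):
        task = session.task_mask
        acc = 100.0 * float((session.prediction[task] == session.label[task]).mean())
        assert session.accuracy_pct == pytest.approx(acc)

    def test_zero_activation_chance_level(self, layout, null_params, trained):
        sel, model = trained
        run = generate_run(make_run_spec(run_index=2, seed=5), layout, null_params, seed=5)
        res = run_online_session(run, sel, model)
        n = int(res.task_mask.sum())
        half_width = 100 * 1.96 * np.sqrt(0.25 / n)
        assert abs(res.accuracy_pct - 50.0) <= half_width + 1e-9

    def test_label_permutation_chance_level(self, session):
        rng = np.random.default_rng(0)
        task = session.task_mask
        perm = rng.permutation(session.label[task])
        acc = 100.0 * float((session.prediction[task] == perm).mean())
        n = int(task.sum())
        assert abs(acc - 50.0) <= 100 * 1.96 * np.sqrt(0.25 / n)

    def test_online_equals_offline_replay(self, test_run, trained):
        """Oracle: batch recomputation with per-block bias offsets."""
        selector, model = trained
        res = run_online_session(test_run, selector, model)
        ft = extract_features(test_run)
        vals = decision_values(model, selector.transform(ft.X))
        bias, expected = 0.0, []
        for b in np.unique(ft.block_index):
            m = ft.block_index == b
            if ft.block_kind[m][0] == "rest":
                bias = rest_bias(vals[m])
            else:
                expected.extend(np.where(vals[m] - bias >= 0, "right", "left"))
        task = res.task_mask
        np.testing.assert_array_equal(res.prediction[task], np.array(expected, dtype=object))

    def test_bias_correction_is_pure_shift(self, session):
        task = session.task_mask
        for b in np.unique(session.block_index[task]):
            m = session.block_index == b
            shift = session.raw_value[m] - session.corrected_value[m]
            np.testing.assert_allclose(shift, shift[0], atol=1e-12)

    def test_thermometer_trace_derivable(self, session):
        from nirsbci.session import ThermometerState, step_thermometer

        s = ThermometerState()
        for i in range(len(session.second)):
            in_task = session.block_kind[i] == "task"
            ended = i + 1 >= len(session.second) or (
                session.block_index[i + 1] != session.block_index[i]
            )
            correct = in_task and session.prediction[i] == session.label[i]
            s = step_thermometer(s, bool(correct), in_task, bool(ended))
            assert s.grade == session.thermometer[i]

    def test_thermometer_zero_during_rest(self, session):
        assert not session.thermometer[session.block_kind == "rest"].any()

    def test_layout_mismatch_rejected(self, trained):
        from nirsbci import build_checkerboard_layout

        sel, model = trained
        small = build_checkerboard_layout(4, 4, 1, 25)
        run = generate_run(make_run_spec(seed=0), small, seed=0)
        with pytest.raises(ValueError):
            run_online_session(run, sel, model)


class TestCrossvalidate:
    def test_fold_sizes(self, layout):
        rng = np.random.default_rng(0)
        from nirsbci.features import FeatureTable

        table = FeatureTable(
            second=np.arange(1, 101),
            X=rng.normal(size=(100, 48)) + np.repeat([0, 6], 50)[:, None],
            label=np.repeat(["left", "right"], 50),
            block_kind=np.full(100, "task"),
            block_index=np.zeros(100, dtype=int),
        )
        mean, sd, accs = crossvalidate_5fold(table, layout, seed=0)
        assert len(accs) == 5

    def test_separable_is_100(self, layout):
        from nirsbci.features import FeatureTable

        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 48))
        X[:, 10] += np.repeat([0.0, 50.0], 50)  # one perfectly separating channel
        table = FeatureTable(
            second=np.arange(1, 101),
            X=X,
            label=np.repeat(["left", "right"], 50),
            block_kind=np.full(100, "task"),
            block_index=np.zeros(100, dtype=int),
        )
        mean, sd, _ = crossvalidate_5fold(table, layout, seed=0)
        assert mean == pytest.approx(100.0)
        assert sd == pytest.approx(0.0)

    def test_seed_determinism(self, layout, me_features):
        a = crossvalidate_5fold(me_features, layout, seed=7)
        b = crossvalidate_5fold(me_features, layout, seed=7)
        assert a == b

    def test_too_few_samples(self, layout):
        from nirsbci.features import FeatureTable

        table = FeatureTable(
            second=np.arange(1, 5),
            X=np.zeros((4, 48)),
            label=np.array(["left", "right", "left", "right"]),
            block_kind=np.full(4, "task"),
            block_index=np.zeros(4, dtype=int),
        )
        with pytest.raises(ValueError, match="too few"):
            crossvalidate_5fold(table, layout, seed=0)


class TestRunExperiment:
    def test_experiment_1_schedule_and_no_leakage(self, layout):
        runs = generate_subject(experiment_plan(1), layout, seed=3)
        result = run_experiment(experiment_plan(1), runs)
        assert set(result.sessions) == {3, 4, 5}
        assert result.sessions[3].model_runs == (1, 2)
        assert result.sessions[4].model_runs == (2, 3)
        assert result.sessions[5].model_runs == (3, 4)
        for r, sess in result.sessions.items():
            assert r not in sess.model_runs

    def test_experiment_2_run5_uses_last_two_mi_runs(self, layout):
        runs = generate_subject(experiment_plan(2), layout, seed=3)
        result = run_experiment(experiment_plan(2), runs)
        assert result.sessions[2].model_runs == (1,)
        assert result.sessions[5].model_runs == (3, 4)

    def test_experiment_3_requires_sic(self, layout):
        runs = generate_subject(experiment_plan(3), layout, seed=3)
        with pytest.raises(ValueError, match="subject-independent"):
            run_experiment(experiment_plan(3), runs)

    def test_experiment_3_frozen_model(self, layout, trained):
        runs = generate_subject(experiment_plan(3), layout, seed=3)
        result = run_experiment(experiment_plan(3), runs, sic=trained)
        assert set(result.sessions) == {2, 3, 4, 5}
        for sess in result.sessions.values():
            assert sess.model_runs == trained[1].run_indices


class TestChannelTmap:
    def test_strong_activation_flagged(self, layout, quiet_params):
        run = generate_run(make_run_spec(seed=3), layout, quiet_params, seed=3)
        # tiny noise so the t statistic is defined but enormous on active channels
        run.hbo += np.random.default_rng(0).normal(0, 1e-6, run.hbo.shape)
        table = channel_tmap(run, alpha=0.001)
        assert table["significant"].any()

    def test_constant_channel_na(self, layout, null_params):
        run = generate_run(make_run_spec(seed=4), layout, null_params, seed=4)
        run.hbo[:, 0] = 0.0  # constant channel -> constant per-second features
        table = channel_tmap(run, alpha=0.05)
        ch1 = table[table["channel"] == 1]
        assert ch1["na"].all()
        assert not ch1["significant"].any()

    def test_nonzero_constant_channel_no_crash(self, layout, null_params):
        # a non-zero constant raw channel still yields defined statistics
        # (1-s windows alternate between 7 and 8 samples at 7.69 Hz)
        run = generate_run(make_run_spec(seed=4), layout, null_params, seed=4)
        run.hbo[:, 0] = 5.0
        table = channel_tmap(run, alpha=0.05)
        assert len(table) == 96

    def test_null_calibration_small(self, layout, null_params):
        """Unadjusted FPR across channels is near alpha (quick 30-seed check)."""
        alpha, flags, total = 0.05, 0, 0
        for seed in range(30):
            run = generate_run(make_run_spec(seed=seed), layout, null_params, seed=seed)
            table = channel_tmap(run, alpha=alpha, adjust=False)
            flags += int(table["significant"].sum())
            total += len(table)
        rate = flags / total
        se = np.sqrt(alpha * (1 - alpha) / total)
        assert abs(rate - alpha) < 4 * se
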