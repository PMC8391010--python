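import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cuffbp.models import ModelSpec, build_model
from cuffbp.synth import SynthConfig, generate_record
from cuffbp.train import (
    TrainConfig,
    ansi_compliant,
    concat_datasets,
    evaluate_direct,
    evaluate_sequence,
    flops_estimate,
    loo_cv,
    mae,
    rmse,
    train,
    training_steps,
)
from cuffbp.windows import (
    WindowedDataset,
    denormalize_abp,
    fit_norm_stats,
    make_direct_windows,
    make_sequence_windows,
    normalize,
)


class TestMetrics:
    def test_perfect_prediction(self):
        x = np.array([1.0, 2.0, 3.0])
        assert mae(x, x) == 0.0 and rmse(x, x) == 0.0

    def test_direct_substitution(self):
        pred, target = np.array([104.0, 114.0]), np.array([100.0, 120.0])
        assert mae(pred, target) == pytest.approx(5.0)
        assert rmse(pred, target) == pytest.approx(np.sqrt(26.0))

    @given(st.integers(0, 2**31 - 1), st.integers(1, 50))
    def test_mae_never_exceeds_rmse(self, seed, n):
        r = np.random.default_rng(seed)
        pred, target = r.standard_normal(n), r.standard_normal(n)
        assert mae(pred, target) <= rmse(pred, target) + 1e-12

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mae(np.zeros(3), np.zeros(4))


class TestTrainingSteps:
    @pytest.mark.parametrize(
        "epochs, n, batch, expected",
        [(10, 3200, 32, 1000), (1, 32, 32, 1), (3, 100, 32, 9)],
    )
    def test_drop_last_step_count(self, epochs, n, batch, expected):
        assert training_steps(epochs, n, batch) == expected

    def test_batch_larger_than_dataset(self):
        with pytest.raises(ValueError, match="exceeds"):
            training_steps(1, 10, 32)


class TestAnsi:
    def test_all_zero_differences_compliant(self):
        ok, (m, s) = ansi_compliant(np.zeros(10))
        assert ok and m == 0.0 and s == 0.0

    def test_biased_mean_non_compliant(self):
        ok, (m, s) = ansi_compliant(6.0 + 0.5 * np.random.default_rng(0).standard_normal(100))
        assert not ok and m > 5

    def test_inclusive_boundary(self):
        d = np.sqrt(48.0)  # four points 4 +/- d: mean 4, sample sd exactly 8
        errors = np.array([4 - d, 4 - d, 4 + d, 4 + d])
        ok, (m, s) = ansi_compliant(errors)
        assert ok and m == pytest.approx(4.0) and s == pytest.approx(8.0)

    def test_needs_two_measurements(self):
        with pytest.raises(ValueError):
            ansi_compliant(np.array([1.0]))


class TestFlops:
    @pytest.mark.parametrize(
        "family, length, channels, kernel, expected",
        [
            ("fc", 625, 1, 3, 625),
            ("fc", 625, 2, 3, 2500),
            ("lstm", 625, 1, 3, 625),
            ("lstm", 625, 2, 3, 2500),
            ("wavenet", 625, 1, 3, 1875),
            ("wavenet", 625, 2, 3, 7500),
            ("resnet_lstm", 625, 2, 3, 7500),
        ],
    )
    def test_printed_complexity_formula(self, family, length, channels, kernel, expected):
        assert flops_estimate(family, length, channels, kernel) == expected

    def test_unknown_family(self):
        with pytest.raises(ValueError):
            flops_estimate("transformer", 625, 1)


def _linear_dataset(n=200, seed=0):
    """Direct-setup windows whose targets are a linear functional of the
    input: a sanity fixture any model should fit."""
    r = np.random.default_rng(seed)
    x = r.standard_normal((n, 625, 1))
    w = np.linspace(0, 1, 625)
    y0 = 0.5 + 0.1 * (x[:, :, 0] @ w) / np.sqrt((w**2).sum())
    targets = np.stack([y0, y0 - 0.2], axis=1)
    from cuffbp.windows import NormStats

    return WindowedDataset(
        inputs=x,
        targets=targets,
        patient_ids=np.full(n, "p0", dtype=object),
        setup="direct",
        stats=NormStats(0.0, 1.0, 50.0, 150.0),
        t_indices=np.arange(n) * 625,
    )


class TestTrain:
    def test_tiny_fc_learns_linear_mapping(self):
        ds = _linear_dataset()
        tr, va = ds.subset(np.arange(160)), ds.subset(np.arange(160, 200))
        spec = ModelSpec(family="fc", setup="direct", fc_layers=(16,), channels=1)
        model = build_model(spec, seed=0)
        cfg = TrainConfig(learning_rate=0.003, batch_size=16, epochs=8, seed=0)
        first = evaluate_direct(model, va).mae_sbp
        hist = train(model, tr, cfg)
        last = evaluate_direct(model, va).mae_sbp
        assert last < first
        assert hist["steps"] == training_steps(8, 160, 16)

    def test_same_seed_reproduces_weights_exactly(self):
        ds = _linear_dataset(n=64)
        spec = ModelSpec(family="fc", setup="direct", fc_layers=(8,), channels=1)
        cfg = TrainConfig(batch_size=16, epochs=2, seed=3)
        runs = []
        for _ in range(2):
            m = build_model(spec, seed=3)
            train(m, ds, cfg)
            runs.append([p.value.copy() for p in m.parameters()])
        for a, b in zip(*runs):
            np.testing.assert_array_equal(a, b)

    def test_equal_update_counts_across_batch_sizes(self):
        ds = _linear_dataset(n=128)
        spec = ModelSpec(family="fc", setup="direct", fc_layers=(8,), channels=1)
        histories = {}
        for batch, epochs in ((16, 2), (32, 4)):  # both: 16 updates
            m = build_model(spec, seed=0)
            histories[batch] = train(
                m, ds, TrainConfig(batch_size=batch, epochs=epochs, seed=0)
            )
        assert histories[16]["steps"] == histories[32]["steps"] == 16

    def test_setup_mismatch_rejected(self):
        ds = _linear_dataset(n=64)
        model = build_model(
            ModelSpec(family="lstm_stack", setup="sequence", lstm_width=4), seed=0
        )
        with pytest.raises(ValueError, match="setup"):
            train(model, ds, TrainConfig(batch_size=16, epochs=1))


class _OracleDirect:
    """Stub predicting the exact normalized targets of the dataset it was
    built from (keyed on window bytes)."""

    def __init__(self, *datasets):
        self.table = {}
        for ds in datasets:
            for xw, t in zip(ds.inputs, ds.targets):
                self.table[xw.tobytes()] = t

    def predict(self, x, batch_size=256):
        return np.stack([self.table[w.tobytes()] for w in x])


class _BiasedOracle(_OracleDirect):
    def __init__(self, offset_norm, *datasets):
        super().__init__(*datasets)
        self.offset = offset_norm

    def predict(self, x, batch_size=256):
        return super().predict(x) + self.offset


class TestEvaluate:
    def test_oracle_model_scores_zero(self, cleaned_record):
        ds = make_direct_windows(cleaned_record["norm"], cleaned_record["ann"])
        res = evaluate_direct(_OracleDirect(ds), ds)
        assert res.mae_sbp == res.mae_dbp == res.rmse_sbp == res.rmse_dbp == 0.0

    def test_constant_predictor_closed_form(self, cleaned_record):
        ds = make_direct_windows(cleaned_record["norm"], cleaned_record["ann"])

        class Const:
            def predict(self, x, batch_size=256):
                return np.tile(ds.targets.mean(axis=0), (len(x), 1))

        res = evaluate_direct(Const(), ds)
        targ = denormalize_abp(ds.targets, ds.stats)
        expected_sbp = np.abs(targ[:, 0] - targ[:, 0].mean()).mean()
        assert res.mae_sbp == pytest.approx(expected_sbp)
        assert res.mae_sbp <= res.rmse_sbp

    def test_sequence_identity_oracle_zero_beat_errors(self):
        rec, _ = generate_record(SynthConfig(duration_minutes=1.0, seed=9))
        norm = normalize(rec, fit_norm_stats([rec]))
        ds = make_sequence_windows(norm, stride=1)

        class SeqOracle:
            def predict_point(self, x, batch_size=256):
                return ds.targets

        res = evaluate_sequence(SeqOracle(), ds)
        assert res.signal_mae == 0.0 and res.signal_rmse == 0.0
        assert res.mae_sbp == 0.0 and res.mae_dbp == 0.0


@pytest.fixture(scope="module")
def patients():
    from cuffbp.beats import detect_beats
    from cuffbp.synth import generate_patients

    cohort = generate_patients(5, SynthConfig(duration_minutes=2.0), seed=1)
    return [(rec, detect_beats(rec.channels["ABP"], rec.fs)) for rec, _ in cohort]


class TestLeaveOneOut:
    def test_five_patients_five_folds_each_held_out_once(self, patients):
        spec = ModelSpec(family="fc", setup="direct", channels=1)
        folds, overall = loo_cv(
            patients, spec, TrainConfig(epochs=1),
            model_factory=lambda tr, ho: _OracleDirect(tr, ho),
        )
        assert len(folds) == 5
        held_out = [list(f.per_patient) for f in folds]
        assert sorted(pid for (f,) in held_out for pid in [f]) == sorted(
            r.patient_id for r, _ in patients
        )

    def test_oracle_model_gives_zero_overall(self, patients):
        spec = ModelSpec(family="fc", setup="direct", channels=1)
        _, overall = loo_cv(
            patients, spec, TrainConfig(epochs=1),
            model_factory=lambda tr, ho: _OracleDirect(tr, ho),
        )
        assert overall["mae_sbp"] == 0.0 and overall["mae_dbp"] == 0.0

    def test_overall_is_unweighted_mean_of_fold_maes(self, patients):
        """Folds with constant per-fold bias b_i have MAE b_i (in mmHg); the
        overall MAE must equal mean(b_i) regardless of fold sizes."""
        spec = ModelSpec(family="fc", setup="direct", channels=1)
        biases_mmhg = [2.0, 4.0, 6.0, 8.0, 10.0]
        calls = iter(biases_mmhg)

        def factory(tr, ho):
            b = next(calls)
            span = ho.stats.abp_max - ho.stats.abp_min
            return _BiasedOracle(b / span, tr, ho)

        folds, overall = loo_cv(patients, spec, TrainConfig(epochs=1),
                                model_factory=factory)
        for f, b in zip(folds, biases_mmhg):
            assert f.mae_sbp == pytest.approx(b)
        assert overall["mae_sbp"] == pytest.approx(np.mean(biases_mmhg))

    def test_single_patient_rejected(self, patients):
        with pytest.raises(ValueError, match="at least 2"):
            loo_cv(patients[:1], ModelSpec(family="fc", setup="direct"),
                   TrainConfig())

    def test_heldout_patient_absent_from_fold_stats(self, patients):
        """Normalization statistics of each fold must come from the training
        patients only."""
        spec = ModelSpec(family="fc", setup="direct", channels=1)
        seen_stats = []

        def factory(tr, ho):
            seen_stats.append(tr.stats)
            return _OracleDirect(tr, ho)

        loo_cv(patients, spec, TrainConfig(epochs=1), model_factory=factory)
        for i, stats in enumerate(seen_stats):
            others = [r for j, (r, _) in enumerate(patients) if j != i]
            expected = fit_norm_stats(others)
            assert stats.abp_min == expected.abp_min
            assert stats.abp_max == expected.abp_max


def test_concat_datasets_rejects_mismatched_setups(cleaned_record):
    d_direct = make_direct_windows(cleaned_record["norm"], cleaned_record["ann"])
    d_seq = make_sequence_windows(cleaned_record["norm"], stride=100)
    with pytest.raises(ValueError):
        concat_datasets([d_direct, d_seq])
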