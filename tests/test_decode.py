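import math
from itertools import product

import numpy as np
import pytest

from voltfield.decode import (
    DecoderModel,
    IneligibleRecordingError,
    decode_counts_batch,
    decode_trial,
    evaluate_decoding,
    fit_decoder,
    session_counts,
)
from voltfield.io_model import OdorDelayAxis
from voltfield.synthgen import SynthConfig, generate_cell_session

from conftest import make_session, make_trial


def toy_model(rates, n_bins, prior=None, sigma_s=3.0, bin_ms=100):
    """DecoderModel over an arbitrary extended template (no dropped bins)."""
    rates = np.asarray(rates, dtype=float)
    ext = np.arange(len(rates))
    if prior is None:
        prior = np.full(len(rates), 1.0 / len(rates))
    axis = OdorDelayAxis(start_ms=1000, end_ms=1000 + n_bins * bin_ms, bin_ms=bin_ms)
    return DecoderModel(
        rates_hz=np.maximum(rates, 1e-6),
        log_prior=np.log(prior),
        retained_ext=ext,
        n_bins=n_bins,
        tau_s=bin_ms / 1000.0,
        sigma_s=sigma_s,
        axis=axis,
        train_indices=np.arange(0),
        test_indices=np.arange(0),
        dropped_bins=np.array([], dtype=int),
    )


def brute_force_decode(model, counts):
    """Independent oracle: full normalized posterior in linear space,
    exhaustive maximization, earliest bin on ties."""
    lam = [model.tau_s * r for r in model.rates_hz]
    prior = [math.exp(lp) for lp in model.log_prior]
    centers = [(e + 0.5) * model.tau_s for e in model.retained_ext]
    decoded = []
    prev = None
    for s in counts:
        post = []
        for k in range(len(lam)):
            p = prior[k] * (lam[k] ** s) * math.exp(-lam[k]) / math.gamma(s + 1)
            if prev is not None:
                p *= math.exp(-((centers[k] - prev) ** 2) / (2 * model.sigma_s**2))
            post.append(p)
        total = sum(post)
        post = [p / total for p in post]  # the normalization C
        best, best_p = 0, post[0]
        for k in range(1, len(post)):
            if post[k] > best_p:
                best, best_p = k, post[k]
        decoded.append(model.retained_ext[best])
        prev = centers[best]
    return decoded


class TestOracle:
    @pytest.mark.parametrize("n_bins", [1, 2, 3])
    def test_matches_brute_force_exhaustive(self, n_bins):
        rng = np.random.default_rng(0)
        for rep in range(5):
            rates = rng.uniform(0.5, 40.0, size=2 * n_bins)
            model = toy_model(rates, n_bins)
            for counts in product(range(4), repeat=n_bins):
                got = decode_trial(model, np.array(counts))
                want = brute_force_decode(model, counts)
                assert list(got) == want

    def test_matches_with_nonuniform_prior(self):
        rng = np.random.default_rng(1)
        n_bins = 4
        for rep in range(20):
            rates = rng.uniform(0.5, 40.0, size=2 * n_bins)
            p = rng.random(2 * n_bins) + 0.1
            model = toy_model(rates, n_bins, prior=p / p.sum())
            counts = rng.integers(0, 4, size=n_bins)
            assert list(decode_trial(model, counts)) == brute_force_decode(model, counts)


class TestDecodeBehavior:
    def test_sharp_peak_high_sigma(self):
        nb = 12
        rates = np.full(2 * nb, 1.0)
        rates[10] = 80.0
        model = toy_model(rates, nb, sigma_s=1e9)
        counts = np.zeros(nb, dtype=int)
        counts[10] = 8
        decoded = decode_trial(model, counts)
        assert decoded[10] == 10

    def test_zero_spikes_uniform_pins_earliest(self):
        nb = 10
        model = toy_model(np.full(2 * nb, 5.0), nb)
        decoded = decode_trial(model, np.zeros(nb, dtype=int))
        assert decoded[0] == 0
        assert np.all(decoded == 0)  # continuity keeps it at the first bin

    def test_tiny_sigma_constant_after_first(self):
        rng = np.random.default_rng(2)
        nb = 8
        model = toy_model(rng.uniform(1, 30, 2 * nb), nb, sigma_s=1e-6)
        counts = rng.integers(0, 3, size=nb)
        decoded = decode_trial(model, counts)
        assert len(set(decoded[1:].tolist())) == 1

    def test_odor_relabel_symmetry(self):
        cfg = SynthConfig(seed=12, n_trials=18, baseline_rate_hz=8, field="odorA",
                          field_gain=6.0, synth_dff=False)
        sess, _ = generate_cell_session(cfg)
        swapped = make_session(
            [
                make_trial(
                    t.spike_times,
                    odor1_id="B" if t.odor1_id == "A" else "A",
                    odor2_id=t.odor2_id,
                )
                for t in sess.trials
            ]
        )
        m1 = fit_decoder(sess)
        m2 = fit_decoder(swapped)
        counts = session_counts(sess)[m1.test_indices]
        d1 = decode_counts_batch(m1, counts)
        d2 = decode_counts_batch(m2, counts)
        nb = m1.n_bins
        # swapping odor labels mirrors the decoded halves
        assert np.array_equal((d1 + nb) % (2 * nb), d2)


class TestFit:
    def _session(self, odors, n_spikes=3):
        trials = []
        for i, o in enumerate(odors):
            trials.append(make_trial(1500 + np.arange(n_spikes) * 40 + i, odor1_id=o))
        return make_session(trials)

    def test_nine_trials_ineligible(self):
        with pytest.raises(IneligibleRecordingError, match="trials"):
            fit_decoder(self._session("ABABABABA"))

    def test_insufficient_training_odor(self):
        # 12 trials, training = first 8; only one B in training
        with pytest.raises(IneligibleRecordingError, match="training"):
            fit_decoder(self._session("AAAAAAAB" + "BBBB"))

    def test_equal_odor_counts_uniform_prior(self):
        sess = self._session("ABABABABABAB")
        model = fit_decoder(sess)
        assert np.allclose(model.log_prior, model.log_prior[0])

    def test_silent_bins_dropped(self):
        # spikes confined to the first ~0.9 s of odor; later bins empty
        trials = [
            make_trial(1000 + np.arange(10) * 90, odor1_id=o) for o in "ABABABABABAB"
        ]
        model = fit_decoder(make_session(trials), smooth_points=1)
        assert len(model.dropped_bins) > 0
        assert np.all(model.dropped_bins >= 9)
        # retained candidates exclude both halves of each dropped bin
        nb = model.n_bins
        for b in model.dropped_bins:
            assert b not in model.retained_ext
            assert (b + nb) not in model.retained_ext

    def test_train_test_split_two_thirds(self):
        sess = self._session("ABAB" * 3)
        model = fit_decoder(sess)
        assert len(model.train_indices) == 8
        assert len(model.test_indices) == 4


class TestEvaluate:
    def test_mirrored_bin_zero_error_zero_accuracy(self):
        nb = 6
        model = toy_model(np.full(2 * nb, 1.0), nb)
        decoded = (np.arange(nb) + nb)[None, :]  # correct time, wrong half
        from voltfield.decode import _metrics

        err, acc = _metrics(model, decoded, ["A"])
        assert err == 0.0
        assert acc == 0.0

    def test_perfect_template_match(self):
        # deterministic high-count emissions from a graded template
        nb = 12
        ra = np.linspace(2, 60, nb)
        template = np.concatenate([ra, ra[::-1]]) * 10
        model = toy_model(template, nb)
        counts = np.round(model.tau_s * ra * 10).astype(int)
        res = evaluate_decoding(model, counts[None, :], ["A"], seed=0, n_surrogates=50)
        assert res.time_error_ms == 0.0
        assert res.odor_accuracy == 1.0
        assert res.chance_time_error_ms.shape == (50,)

    def test_chance_shapes_and_bounds(self):
        cfg = SynthConfig(seed=13, n_trials=15, baseline_rate_hz=8, synth_dff=False)
        sess, _ = generate_cell_session(cfg)
        model = fit_decoder(sess)
        counts = session_counts(sess)[model.test_indices]
        odors = [sess.trials[i].odor1_id for i in model.test_indices]
        res = evaluate_decoding(model, counts, odors, seed=0, n_surrogates=40)
        assert 0.0 <= res.odor_accuracy <= 1.0
        assert 0.0 <= res.time_error_ms <= 3000.0
        assert len(res.chance_time_error_ms) == 40
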