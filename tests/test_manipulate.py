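import numpy as np
import pytest

from convoturn.audio import AudioTrack, rms
from convoturn.fto import HIN_LOGISTIC, NHQ_LOGISTIC, sample_ftos, summarize
from convoturn.manipulate import (
    ManipulationScheme,
    RenderConfig,
    _compress_pause_duration,
    compress_pauses,
    equalize_loudness,
    make_paired_nhq_hin,
    manipulate_segment,
)
from convoturn.states import build_ipus, classify_states
from convoturn.synthetic import ConvGenParams, generate_synthetic_conversation
from convoturn.timeline import IPU, Turn
from convoturn.vad import detect_voice_activity

SR = 48000


class TestSchemeConfig:
    def test_constant_schemes_carry_no_distributions(self):
        with pytest.raises(ValueError):
            ManipulationScheme("conLow", constant_fto_ms=50.0, source_dist=NHQ_LOGISTIC)
        with pytest.raises(ValueError):
            ManipulationScheme("NHQ", constant_fto_ms=190.0)
        with pytest.raises(ValueError):
            ManipulationScheme("HIN", source_dist=NHQ_LOGISTIC)

    def test_factories(self):
        assert ManipulationScheme.conlow().constant_fto_ms == 50.0
        assert ManipulationScheme.connhq().constant_fto_ms == 190.0
        assert ManipulationScheme.hin().target_dist == HIN_LOGISTIC


class TestEqualizeLoudness:
    def test_sine_hits_target(self):
        t = np.arange(SR) / SR
        x = 0.8 * np.sin(2 * np.pi * 220 * t)
        mask = np.ones(SR, dtype=bool)
        out, gain = equalize_loudness(x, mask, 0.05)
        assert rms(out[mask]) == pytest.approx(0.05, rel=1e-6)

    def test_gain_one_when_already_at_target(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=SR)
        x *= 0.05 / rms(x)
        _, gain = equalize_loudness(x, np.ones(SR, dtype=bool), 0.05)
        assert gain == pytest.approx(1.0, rel=1e-9)

    def test_rms_over_ipus_not_whole_turn(self):
        """With a silent pause inside, the gain targets speech samples only."""
        x = np.zeros(3 * SR)
        mask = np.zeros(3 * SR, dtype=bool)
        x[:SR] = 0.2
        x[2 * SR :] = 0.2
        mask[:SR] = True
        mask[2 * SR :] = True
        out, gain = equalize_loudness(x, mask, 0.05)
        # hand-computed: speech RMS is 0.2 -> gain 0.25
        assert gain == pytest.approx(0.25)
        assert rms(out[mask]) == pytest.approx(0.05)
        assert np.all(out[SR : 2 * SR] == 0.0)

    def test_silent_turn_rejected(self):
        with pytest.raises(ValueError, match="silent"):
            equalize_loudness(np.zeros(100), np.ones(100, dtype=bool), 0.05)


class TestCompressPauses:
    @pytest.mark.parametrize(
        "pause_ms, expected_ms",
        [(1000.0, 250.0), (300.0, 300.0), (600.0, 150.0), (250.0, 250.0), (301.0, 150.5)],
    )
    def test_halving_rule(self, pause_ms, expected_ms):
        assert _compress_pause_duration(pause_ms) == pytest.approx(expected_ms)

    def test_turn_geometry(self):
        turn = Turn(
            "A",
            ipus=[IPU("A", 0.0, 1.0), IPU("A", 2.0, 3.0)],  # 1000 ms pause
        )
        out = compress_pauses(turn)
        assert out.start == 0.0
        assert out.ipus[1].start == pytest.approx(1.25)
        assert out.end == pytest.approx(2.25)  # shifted left by 750 ms
        assert out.internal_pauses == [pytest.approx((1.0, 1.25))]
        assert out.speech_duration == pytest.approx(turn.speech_duration)


@pytest.fixture(scope="module")
def conversation():
    return generate_synthetic_conversation(ConvGenParams(n_transfers=14), seed=42)


class TestManipulateSegment:
    @pytest.mark.parametrize("name, constant", [("conNHQ", 190.0), ("conLow", 50.0)])
    def test_constant_schemes_realize_exact_ftos(self, conversation, name, constant):
        a, b, tl = conversation
        r = manipulate_segment(a, b, tl, ManipulationScheme.by_name(name), seed=0)
        assert len(r.realized_ftos) == len(tl.turns) - 1
        assert np.allclose(r.realized_ftos, constant, atol=1e-6)
        assert np.std(r.realized_ftos) == pytest.approx(0.0, abs=1e-9)

    def test_leading_silence_200ms(self, conversation):
        a, b, tl = conversation
        r = manipulate_segment(a, b, tl, ManipulationScheme.connhq(), seed=0)
        lead = int(round(0.2 * r.sample_rate))
        first = np.flatnonzero(np.abs(r.waveform) > 1e-9)[0]
        assert abs(first - lead) <= 1

    def test_no_long_pause_survives(self):
        params = ConvGenParams(
            n_transfers=14, internal_pause_prob=1.0, internal_pause_range_ms=(350, 2000)
        )
        a, b, tl = generate_synthetic_conversation(params, seed=3)
        r = manipulate_segment(a, b, tl, ManipulationScheme.connhq(), seed=0)
        pauses = [
            (pe - ps) * 1000
            for t in r.realized_timeline.turns
            for ps, pe in t.internal_pauses
        ]
        assert pauses and max(pauses) < 300.0

    def test_speech_content_conserved(self, conversation):
        a, b, tl = conversation
        r = manipulate_segment(a, b, tl, ManipulationScheme.conlow(), seed=0)
        in_speech = sum(t.speech_duration for t in tl.turns)
        out_speech = sum(t.speech_duration for t in r.realized_timeline.turns)
        assert out_speech == pytest.approx(in_speech, abs=2e-3)

    def test_silence_between_turns_is_zero(self, conversation):
        a, b, tl = conversation
        r = manipulate_segment(a, b, tl, ManipulationScheme.connhq(), seed=0)
        tlr = r.realized_timeline
        for f, t0, t1 in zip(tlr.ftos, tlr.turns[:-1], tlr.turns[1:]):
            if f.value > 20:  # a genuine gap
                i0 = int((t0.end + 0.006) * r.sample_rate)
                i1 = int((t1.start - 0.006) * r.sample_rate)
                if i1 > i0:
                    assert np.all(r.waveform[i0:i1] == 0.0)

    def test_nhq_scheme_distribution_contract(self, conversation):
        """Pooled NHQ realizations refit close to the source distribution."""
        a, b, tl = conversation
        pooled = []
        for seed in range(80):
            r = manipulate_segment(a, b, tl, ManipulationScheme.nhq(), seed=seed)
            pooled.extend(r.realized_ftos)
        from convoturn.fto import fit_logistic

        fit = fit_logistic(np.asarray(pooled))
        # clamping of extreme negative draws trims the lower tail slightly
        assert fit.mu == pytest.approx(NHQ_LOGISTIC.mu, abs=30.0)
        assert fit.sigma == pytest.approx(NHQ_LOGISTIC.sigma, rel=0.15)

    def test_determinism(self, conversation):
        a, b, tl = conversation
        r1 = manipulate_segment(a, b, tl, ManipulationScheme.nhq(), seed=11)
        r2 = manipulate_segment(a, b, tl, ManipulationScheme.nhq(), seed=11)
        assert np.array_equal(r1.waveform, r2.waveform)
        assert r1.realized_ftos == r2.realized_ftos

    def test_full_loop_roundtrip_on_rendered_stems(self, conversation):
        """VAD + classification on the rendered stems recovers 190 ms FTOs."""
        a, b, tl = conversation
        r = manipulate_segment(a, b, tl, ManipulationScheme.connhq(), seed=0)
        masks = {
            spk: detect_voice_activity(AudioTrack(w, r.sample_rate, spk))
            for spk, w in r.stems.items()
        }
        det = classify_states(build_ipus(masks["A"]), build_ipus(masks["B"]))
        vals = [f.value for f in det.ftos]
        assert len(vals) == len(r.realized_ftos)
        assert np.allclose(vals, 190.0, atol=10.0)


class TestPairedNhqHin:
    def test_affine_pairing_with_equal_counts(self):
        p = ConvGenParams(n_transfers=13, overlap_within_prob=0.0)
        seg1 = generate_synthetic_conversation(p, seed=1)
        seg2 = generate_synthetic_conversation(p, seed=2)
        r1, r2 = make_paired_nhq_hin(seg1, seg2, seed=5)
        x = np.asarray(r1.realized_ftos)
        y = np.asarray(r2.realized_ftos)
        expect = HIN_LOGISTIC.mu + (HIN_LOGISTIC.sigma / NHQ_LOGISTIC.sigma) * (
            x - NHQ_LOGISTIC.mu
        )
        # up to sample-grid rounding and per-segment clamping of deep overlaps
        bound1 = -0.9 * np.array([t.duration for t in r2.realized_timeline.turns[:-1]]) * 1000
        free = expect > bound1 + 1.0
        assert np.allclose(y[free], expect[free], atol=0.05)

    def test_identity_transform_when_params_equal(self):
        p = ConvGenParams(n_transfers=12, overlap_within_prob=0.0)
        seg1 = generate_synthetic_conversation(p, seed=3)
        seg2 = generate_synthetic_conversation(p, seed=4)
        r1, r2 = make_paired_nhq_hin(
            seg1, seg2, nhq_params=NHQ_LOGISTIC, hin_params=NHQ_LOGISTIC, seed=8
        )
        assert np.allclose(r1.realized_ftos, r2.realized_ftos, atol=0.05)

    def test_hin_median_converges_to_target(self):
        """Across seeds the realized HIN FTO median approaches 454.7 ms."""
        p = ConvGenParams(n_transfers=15, overlap_within_prob=0.0)
        seg1 = generate_synthetic_conversation(p, seed=10)
        seg2 = generate_synthetic_conversation(p, seed=11)
        pooled = []
        for seed in range(60):
            _, r2 = make_paired_nhq_hin(seg1, seg2, seed=seed)
            pooled.extend(r2.realized_ftos)
        s = summarize(pooled)
        se = HIN_LOGISTIC.sigma * 2 / np.sqrt(len(pooled))
        assert s.median == pytest.approx(HIN_LOGISTIC.mu, abs=5 * se)


def test_scheduling_requires_two_turns():
    a, b, tl = generate_synthetic_conversation(
        ConvGenParams(n_transfers=12), seed=0
    )
    tl.turns = tl.turns[:1]
    tl.ftos = []
    tl.overlaps_within = []
    with pytest.raises(ValueError, match="two turns"):
        manipulate_segment(a, b, tl, ManipulationScheme.conlow(), seed=0)
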