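"""Generator behavior: pairing design, signal structure, outcome structure."""

import dataclasses
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import curve_fit

import dyadsync as ds
from dyadsync.synthdata import MEASURES


def _pairs(roster: pd.DataFrame) -> list[frozenset]:
    return [frozenset((a, b)) for a, b in zip(roster["member_a"], roster["member_b"])]


class TestRoster:
    def test_complete_round_robin_on_four(self):
        roster = ds.make_roster(4, 3, conditions=("Gazing",), seed=1)
        assert len(roster) == 6
        assert set(_pairs(roster)) == {
            frozenset(p) for p in combinations(sorted(set(roster["member_a"]) | set(roster["member_b"])), 2)
        }

    def test_odd_count_one_sits_out(self):
        roster = ds.make_roster(5, 1, seed=2)
        assert len(roster) == 2  # 2 dyads, 1 participant on break
        members = set(roster["member_a"]) | set(roster["member_b"])
        assert len(members) == 4

    def test_unique_pairings_brute_force(self):
        """10 participants x 4 rounds: 20 dyads, exhaustively unique."""
        roster = ds.make_roster(10, 4, seed=3)
        assert len(roster) == 20
        pairs = _pairs(roster)
        assert len(set(pairs)) == len(pairs)
        # each participant appears exactly once per round
        for _, rnd in roster.groupby("round"):
            members = list(rnd["member_a"]) + list(rnd["member_b"])
            assert len(members) == len(set(members)) == 10

    def test_infeasible_rounds_raise_unless_repeats_allowed(self):
        with pytest.raises(ValueError, match="infeasible"):
            ds.make_roster(4, 5, seed=0)
        roster = ds.make_roster(4, 5, seed=0, allow_repeats=True)
        assert len(roster) == 10

    def test_sessions_carry_one_condition_each(self):
        roster = ds.make_roster(6, 2, conditions=("Gazing", "JLM"), seed=4)
        per_session = roster.groupby("session")["condition"].nunique()
        assert (per_session == 1).all()
        assert set(roster["condition"]) == {"Gazing", "JLM"}
        # pools are disjoint between sessions
        s0 = set(roster[roster.session == 0]["member_a"]) | set(roster[roster.session == 0]["member_b"])
        s1 = set(roster[roster.session == 1]["member_a"]) | set(roster[roster.session == 1]["member_b"])
        assert not s0 & s1

    def test_no_self_pairing(self):
        roster = ds.make_roster(9, 5, seed=5)
        assert (roster["member_a"] != roster["member_b"]).all()


class TestSmileDyad:
    def test_degenerate_nonsmilers_give_zero_series(self):
        cfg = ds.SimConfig(nonsmiler_prob=1.0)
        a, b = ds.simulate_smile_dyad(cfg, 0.0, seed=0)
        assert not a.values.any() and not b.values.any()
        assert a.n_samples == cfg.n_samples("smile") == 3000

    def test_full_mimicry_every_burst_answered(self):
        """coupling=1: every spontaneous burst is followed by partner activity
        within the mimicry lag window (checked on the emitted series)."""
        cfg = ds.SimConfig(nonsmiler_prob=0.0, smile_burst_rate=3.0)
        a, b, ev_a, ev_b = ds.simulate_smile_dyad(cfg, 1.0, seed=9, return_events=True)
        lag_lo, lag_hi = cfg.mimicry_lag_s
        for series, events in ((b, ev_a), (a, ev_b)):
            for center, _amp, kind in events:
                if kind != "spontaneous":
                    continue
                lo = center + lag_lo - cfg.smile_burst_width_s / 2
                hi = center + lag_hi + cfg.smile_burst_width_s / 2
                if lo >= cfg.duration_s:  # response would fall off the recording
                    continue
                i0 = max(0, int(np.ceil(lo * cfg.smile_rate_hz)))
                i1 = min(series.n_samples, int(np.floor(hi * cfg.smile_rate_hz)) + 1)
                assert series.values[i0:i1].max() > 0

    @given(st.integers(0, 2**31 - 1), st.floats(0, 1))
    def test_bounds_and_length(self, seed, coupling):
        cfg = ds.SimConfig()
        a, b = ds.simulate_smile_dyad(cfg, coupling, seed=seed)
        for s in (a, b):
            assert s.n_samples == 3000
            assert s.values.min() >= 0.0 and s.values.max() <= 100.0

    def test_invalid_coupling_rejected(self):
        with pytest.raises(ValueError, match="coupling"):
            ds.simulate_smile_dyad(ds.SimConfig(), 1.5, seed=0)


class TestHRDyad:
    def test_degenerate_constant_baseline(self):
        cfg = ds.SimConfig(hr_arousal_amp_bpm=0.0, hr_noise_sd=0.0)
        a, b = ds.simulate_hr_dyad(cfg, 0.0, seed=0)
        assert np.allclose(a.values, cfg.hr_baseline_bpm)
        assert np.allclose(b.values, cfg.hr_baseline_bpm)
        assert a.n_samples == 60

    def test_shared_innovations_give_identical_fluctuations(self):
        """c_hr = 1 with identical AR coefficients: the prewhitened residuals
        of the two members coincide (correlation 1 up to float noise)."""
        vals = []
        for seed in range(20):
            a, b = ds.simulate_hr_dyad(ds.SimConfig(), 1.0, seed=seed)
            ra, _ = ds.prewhiten_ar(a)
            rb, _ = ds.prewhiten_ar(b)
            n = min(ra.n_samples, rb.n_samples)
            vals.append(ds.lagged_correlation(ra.values[-n:], rb.values[-n:], 0))
        assert np.min(vals) > 0.999

    def test_nonstationary_ar_rejected(self):
        with pytest.raises(ValueError, match="non-stationary"):
            ds.SimConfig(hr_ar_coef=1.0)

    def test_decay_recovery_from_ensemble_mean(self):
        """A nonlinear fit to the ensemble-mean trajectory recovers the
        arousal amplitude within 20% over 200 dyads."""
        cfg = ds.SimConfig(hr_arousal_amp_bpm=10.0, hr_decay_tau_s=30.0)
        acc = np.zeros(cfg.n_samples("hr"))
        for seed in range(200):
            a, b = ds.simulate_hr_dyad(cfg, 0.0, seed=seed)
            acc += a.values + b.values
        mean_traj = acc / 400.0
        t = np.arange(mean_traj.size) / cfg.hr_rate_hz

        def model(t, base, amp, tau):
            return base + amp * np.exp(-t / tau)

        (base, amp, tau), _ = curve_fit(model, t, mean_traj, p0=(70.0, 5.0, 20.0))
        assert abs(amp - 10.0) < 2.0
        assert abs(base - cfg.hr_baseline_bpm) < 2.0

    def test_hr_positive(self):
        cfg = ds.SimConfig(hr_noise_sd=5.0)
        for seed in range(10):
            a, b = ds.simulate_hr_dyad(cfg, 0.3, seed=seed)
            assert a.values.min() > 0 and b.values.min() > 0


class TestOutcomes:
    def _roster_truth(self, n_dyads, coupling=None, seed=0):
        rng = np.random.default_rng(seed)
        rows = [
            {
                "session": 0,
                "round": 1,
                "dyad_id": f"D{i:03d}",
                "member_a": f"a{i}",
                "member_b": f"b{i}",
                "condition": "Gazing",
                "familiarity_a": 0,
                "familiarity_b": 0,
                "pair_type": "real",
            }
            for i in range(n_dyads)
        ]
        roster = pd.DataFrame(rows)
        c = np.full(n_dyads, 0.5) if coupling is None else coupling
        truth = pd.DataFrame({"dyad_id": roster["dyad_id"], "coupling": c})
        return roster, truth

    def test_no_effects_post_equals_pre(self):
        roster, truth = self._roster_truth(5)
        cfg = ds.SimConfig(
            outcome_effect=0.0, outcome_noise_sd=0.0, condition_effects={}, measures=("closeness", "warmth")
        )
        ratings = ds.simulate_outcomes(roster, truth, cfg, seed=1)
        assert np.allclose(ratings["post"], ratings["pre"])

    def test_closeness_is_integer_in_range(self, small_bundle):
        close = small_bundle.ratings[small_bundle.ratings["measure"] == "closeness"]
        for col in ("pre", "post"):
            v = close[col].to_numpy()
            assert np.all((v >= 1) & (v <= 7))
            assert np.allclose(v, np.round(v))

    def test_all_measures_within_ranges(self, small_bundle):
        for measure, (lo, hi, *_rest) in MEASURES.items():
            rows = small_bundle.ratings[small_bundle.ratings["measure"] == measure]
            v = rows["post"].to_numpy()
            assert np.all((v >= lo) & (v <= hi))

    def test_change_score_regression_recovers_slope(self):
        """Known coupling slope is recovered within 2 SE at 200 dyads."""
        rng = np.random.default_rng(42)
        coupling = np.clip(rng.normal(0.5, 0.25, 200), 0, 1)
        roster, truth = self._roster_truth(200, coupling)
        gamma = 0.5
        cfg = ds.SimConfig(
            outcome_effect=gamma, outcome_noise_sd=0.5, condition_effects={}, measures=("warmth",)
        )
        ratings = ds.simulate_outcomes(roster, truth, cfg, seed=3)
        ratings = ds.standardize(ratings, "warmth")
        changes, _ = ds.dyad_change_scores(ratings)
        data = changes.merge(truth, on="dyad_id")
        X = pd.DataFrame({"const": 1.0, "coupling": data["coupling"]})
        fit = ds.fit_ols(data["change_warmth"], X)
        est = fit["coupling"]
        assert abs(est["estimate"] - gamma) < 2 * est["se"]


class TestStudy:
    def test_same_seed_identical_bundles(self, small_cfg, small_bundle):
        again = ds.simulate_study(dataclasses.replace(small_cfg))
        assert small_bundle.equals(again)

    def test_different_seed_differs(self, small_cfg, small_bundle):
        other = ds.simulate_study(dataclasses.replace(small_cfg, seed=small_cfg.seed + 1))
        assert not small_bundle.equals(other)

    def test_every_dyad_has_one_condition_and_truth(self):
        cfg = ds.SimConfig(
            n_participants=10, n_rounds=3, conditions=("Gazing", "JLM", "Eyes Closed"), seed=2
        )
        bundle = ds.simulate_study(cfg)
        per_dyad = bundle.roster.groupby("dyad_id")["condition"].nunique()
        assert (per_dyad == 1).all()
        assert set(bundle.truth["dyad_id"]) == set(bundle.roster["dyad_id"])
        assert bundle.truth["coupling"].between(0, 1).all()

    def test_signals_exist_for_all_real_dyad_members(self, small_bundle):
        for row in small_bundle.roster.itertuples(index=False):
            for member in (row.member_a, row.member_b):
                for modality in small_bundle.config.modalities:
                    assert (member, row.round, modality) in small_bundle.signals

    def test_nonsmiling_is_a_participant_trait(self):
        """A non-smiler is all-zero in every round, not per recording."""
        cfg = ds.SimConfig(n_participants=8, n_rounds=3, nonsmiler_prob=0.5, seed=13)
        bundle = ds.simulate_study(cfg)
        by_participant = {}
        for (participant, _rnd, modality), s in bundle.signals.items():
            if modality != "smile":
                continue
            by_participant.setdefault(participant, []).append(bool(s.values.any()))
        assert any(not any(v) for v in by_participant.values())  # some non-smilers
        for smiled in by_participant.values():
            assert all(smiled) or not any(smiled)
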