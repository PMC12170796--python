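"""Synthetic dyadic-meditation studies with known ground truth.

The generator emulates a speed-dating-style study: groups of participants are
round-robin paired over several rounds, every session runs one condition
(e.g. a mutual-gaze meditation vs. a "Just-Like-Me" contemplation vs. solitary
eyes-closed), and each dyad produces

* two smile-intensity series (0-100): Poisson-timed half-cosine bursts, where
  a partner's burst is mimicked with a per-dyad probability after a short lag;
* two heart-rate series (bpm): a shared initial-arousal exponential decay on
  top of AR(1) fluctuations whose innovations can be partially shared;
* pre/post partner ratings and a dictator-game allocation whose post-pre
  change depends linearly on the dyad's latent coupling.

All of this is driven by one integer seed expanded into counter-based
substreams, so any dyad can be regenerated in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import as_generator, substream
from .series import SignalSeries

__all__ = [
    "SimConfig",
    "StudyBundle",
    "MEASURES",
    "make_roster",
    "simulate_smile_dyad",
    "simulate_hr_dyad",
    "simulate_outcomes",
    "simulate_study",
]


# measure -> (lo, hi, pre_mean, pre_sd, integer_valued, has_pre)
# Closeness is the 7-point pictorial overlapping-circles scale; sliders are
# 0-100. The dictator allocation (share given to the partner, 0-100) and the
# four emotion sliders are collected after the exercise only.
MEASURES: dict[str, tuple[float, float, float, float, bool, bool]] = {
    "closeness": (1, 7, 2.5, 1.2, True, True),
    "warmth": (0, 100, 55.0, 15.0, False, True),
    "competence": (0, 100, 55.0, 15.0, False, True),
    "attractiveness": (0, 100, 45.0, 15.0, False, True),
    "friendship": (0, 100, 50.0, 15.0, False, True),
    "dictator_give": (0, 100, 45.0, 20.0, False, False),
    "anxious": (0, 100, 30.0, 20.0, False, False),
    "relaxed": (0, 100, 60.0, 20.0, False, False),
    "comfortable": (0, 100, 60.0, 20.0, False, False),
    "happy": (0, 100, 60.0, 20.0, False, False),
}


@dataclass
class SimConfig:
    """Parameters of one synthetic study.

    Rates are in Hz, durations in seconds, smile amplitudes on the 0-100
    intensity scale, HR parameters in bpm. ``condition_effects`` and
    ``outcome_effect`` (the slope of outcome change on latent coupling) are
    expressed in units of each measure's pre-exercise SD, so they read like
    standardized effect sizes.
    """

    n_participants: int = 10
    n_rounds: int = 3
    conditions: tuple[str, ...] = ("Gazing", "JLM")
    allow_repeats: bool = False

    smile_rate_hz: float = 25.0
    hr_rate_hz: float = 0.5
    duration_s: float = 120.0

    smile_burst_rate: float = 8.0  # bursts per minute per person
    smile_burst_amp: float = 70.0
    smile_burst_width_s: float = 2.0
    mimicry_prob: float = 0.3
    mimicry_lag_s: tuple[float, float] = (0.2, 1.0)
    nonsmiler_prob: float = 0.19

    hr_baseline_bpm: float = 77.0
    hr_arousal_amp_bpm: float = 12.0
    hr_decay_tau_s: float = 30.0
    hr_ar_coef: float = 0.5
    hr_noise_sd: float = 1.0
    hr_coupling: float = 0.3

    coupling_sd: float = 0.25
    outcome_effect: float = 0.5
    outcome_noise_sd: float = 0.5
    condition_effects: dict[str, float] = field(
        default_factory=lambda: {"Gazing": 0.57, "JLM": 0.97, "Eyes Closed": 0.0}
    )
    familiar_prob: float = 0.05
    modalities: tuple[str, ...] = ("smile", "hr")
    measures: tuple[str, ...] = tuple(MEASURES)
    seed: int = 0

    def __post_init__(self) -> None:
        self.conditions = tuple(self.conditions)
        self.modalities = tuple(self.modalities)
        self.measures = tuple(self.measures)
        self.mimicry_lag_s = tuple(self.mimicry_lag_s)
        self.validate()

    def validate(self) -> None:
        probs = {
            "mimicry_prob": self.mimicry_prob,
            "nonsmiler_prob": self.nonsmiler_prob,
            "hr_coupling": self.hr_coupling,
            "familiar_prob": self.familiar_prob,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name, v in {
            "smile_rate_hz": self.smile_rate_hz,
            "hr_rate_hz": self.hr_rate_hz,
            "duration_s": self.duration_s,
            "smile_burst_width_s": self.smile_burst_width_s,
            "hr_decay_tau_s": self.hr_decay_tau_s,
        }.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        for name, v in {
            "smile_burst_rate": self.smile_burst_rate,
            "smile_burst_amp": self.smile_burst_amp,
            "hr_arousal_amp_bpm": self.hr_arousal_amp_bpm,
            "hr_noise_sd": self.hr_noise_sd,
            "coupling_sd": self.coupling_sd,
            "outcome_noise_sd": self.outcome_noise_sd,
        }.items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if abs(self.hr_ar_coef) >= 1:
            raise ValueError(f"hr_ar_coef implies a non-stationary AR(1): {self.hr_ar_coef}")
        lo, hi = self.mimicry_lag_s
        if not 0 <= lo <= hi:
            raise ValueError(f"mimicry_lag_s bounds must satisfy 0 <= lo <= hi, got {self.mimicry_lag_s}")
        if self.n_participants < 2:
            raise ValueError("n_participants must be at least 2")
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be at least 1")
        for rate, label in ((self.smile_rate_hz, "smile"), (self.hr_rate_hz, "hr")):
            n = self.duration_s * rate
            if abs(n - round(n)) > 1e-9:
                raise ValueError(f"duration_s * {label} rate must be an integer sample count, got {n}")
        unknown = set(self.modalities) - {"smile", "hr"}
        if unknown:
            raise ValueError(f"unknown modalities: {sorted(unknown)}")
        unknown = set(self.measures) - set(MEASURES)
        if unknown:
            raise ValueError(f"unknown measures: {sorted(unknown)}")

    def n_samples(self, modality: str) -> int:
        rate = self.smile_rate_hz if modality == "smile" else self.hr_rate_hz
        return int(round(self.duration_s * rate))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditions"] = list(self.conditions)
        d["modalities"] = list(self.modalities)
        d["measures"] = list(self.measures)
        d["mimicry_lag_s"] = list(self.mimicry_lag_s)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


@dataclass
class StudyBundle:
    """Roster + signals + ratings + ground truth of one simulated study."""

    roster: pd.DataFrame
    signals: dict[tuple[str, int, str], SignalSeries]
    ratings: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig

    def signal(self, participant: str, round: int, modality: str) -> SignalSeries:
        return self.signals[(participant, int(round), modality)]

    def equals(self, other: "StudyBundle") -> bool:
        if set(self.signals) != set(other.signals):
            return False
        return (
            self.roster.equals(other.roster)
            and self.ratings.equals(other.ratings)
            and self.truth.equals(other.truth)
            and all(s.equals(other.signals[k]) for k, s in self.signals.items())
        )


# ---------------------------------------------------------------------------
# Roster


def _round_robin_schedule(players: list, n_rounds: int, allow_repeats: bool):
    """Circle-method schedule: list of (pairs, sitting_out) per round.

    With an odd head count a phantom "bye" is added; the bye's partner sits
    that round out. Distinct matchings exist for n_rounds <= len(players) - 1
    (even count) or len(players) (odd count).
    """
    ps = list(players)
    if len(ps) % 2:
        ps.append(None)
    n = len(ps)
    max_distinct = n - 1
    if n_rounds > max_distinct and not allow_repeats:
        raise ValueError(
            f"{n_rounds} rounds of distinct pairings are infeasible for "
            f"{len(players)} participants (max {max_distinct}); "
            "pass allow_repeats=True to permit repeat pairings"
        )
    fixed, rest = ps[0], ps[1:]
    schedule = []
    for r in range(n_rounds):
        k = r % (n - 1)
        rot = rest[k:] + rest[:k]
        arr = [fixed] + rot
        pairs, sitting_out = [], None
        for i in range(n // 2):
            a, b = arr[i], arr[n - 1 - i]
            if a is None:
                sitting_out = b
            elif b is None:
                sitting_out = a
            else:
                pairs.append((a, b))
        schedule.append((pairs, sitting_out))
    return schedule


def _draw_familiarity(rng: np.random.Generator, p: float) -> int:
    # 0 = not at all, 1 = moderately, 2 = extremely; familiarity is rare.
    u = rng.random()
    if u >= p:
        return 0
    return 2 if rng.random() < 0.2 else 1


def make_roster(
    n_participants: int,
    n_rounds: int,
    conditions=("Gazing",),
    seed=0,
    allow_repeats: bool = False,
    familiar_prob: float = 0.0,
) -> pd.DataFrame:
    """Round-robin dyad roster, one session per condition.

    Each condition gets its own session with its own pool of
    ``n_participants`` participants (all dyads within a session share the
    session's condition). Within a session, partners are new whenever
    possible; with an odd head count one participant sits out each round.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    rng = as_generator(seed)
    rows = []
    for s, condition in enumerate(conditions):
        players = [f"s{s}p{i:02d}" for i in range(n_participants)]
        order = list(players)
        rng.shuffle(order)
        schedule = _round_robin_schedule(order, n_rounds, allow_repeats)
        for r, (pairs, _sitting_out) in enumerate(schedule, start=1):
            for j, (a, b) in enumerate(pairs):
                a, b = sorted((a, b))
                rows.append(
                    {
                        "session": s,
                        "round": r,
                        "dyad_id": f"S{s}R{r}D{j:02d}",
                        "member_a": a,
                        "member_b": b,
                        "condition": condition,
                        "familiarity_a": _draw_familiarity(rng, familiar_prob),
                        "familiarity_b": _draw_familiarity(rng, familiar_prob),
                        "pair_type": "real",
                    }
                )
    roster = pd.DataFrame(rows)
    bad = roster["member_a"] == roster["member_b"]
    if bad.any():  # pragma: no cover - construction guarantees this
        raise AssertionError("self-pairing in roster")
    return roster


def roster_participants(roster: pd.DataFrame, condition: str | None = None) -> list[str]:
    df = roster if condition is None else roster[roster["condition"] == condition]
    return sorted(set(df["member_a"]) | set(df["member_b"]))


# ---------------------------------------------------------------------------
# Smile signals


def _add_bump(values: np.ndarray, rate_hz: float, center_s: float, amp: float, width_s: float) -> None:
    """Add a half-cosine bump (zero at the edges, ``amp`` at the center)."""
    n = values.size
    half = width_s / 2.0
    i0 = max(0, int(np.ceil((center_s - half) * rate_hz)))
    i1 = min(n - 1, int(np.floor((center_s + half) * rate_hz)))
    if i1 < i0:
        return
    t = np.arange(i0, i1 + 1) / rate_hz
    values[i0 : i1 + 1] += amp * np.cos(np.pi * (t - center_s) / width_s)


def simulate_smile_dyad(
    cfg: SimConfig,
    coupling: float,
    seed=0,
    nonsmiler: tuple[bool, bool] | None = None,
    return_events: bool = False,
):
    """Simulate one dyad's smile-intensity pair.

    Each member emits Poisson-timed half-cosine bursts; with probability
    ``coupling`` a member's spontaneous burst elicits a partner response burst
    after a lag drawn uniformly from ``cfg.mimicry_lag_s``. A member may be a
    non-smiler (all-zero series): drawn with ``cfg.nonsmiler_prob`` unless
    ``nonsmiler`` pins it (used by :func:`simulate_study` to make
    non-smiling a stable participant trait). Values are clipped to [0, 100].
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValueError(f"coupling must be in [0, 1], got {coupling}")
    rng = as_generator(seed)
    n = cfg.n_samples("smile")
    if nonsmiler is None:
        nonsmiler = tuple(rng.random(2) < cfg.nonsmiler_prob)

    spontaneous: list[list[tuple[float, float]]] = [[], []]
    for m in range(2):
        if nonsmiler[m]:
            continue
        k = rng.poisson(cfg.smile_burst_rate * cfg.duration_s / 60.0)
        centers = np.sort(rng.uniform(0.0, cfg.duration_s, k))
        amps = cfg.smile_burst_amp * rng.uniform(0.7, 1.0, k)
        spontaneous[m] = list(zip(centers.tolist(), amps.tolist()))

    events: list[list[tuple[float, float, str]]] = [
        [(c, a, "spontaneous") for c, a in spontaneous[m]] for m in range(2)
    ]
    for m in range(2):
        other = 1 - m
        if nonsmiler[other]:
            continue
        for center, _amp in spontaneous[m]:
            if rng.random() < coupling:
                lag = rng.uniform(*cfg.mimicry_lag_s)
                amp = cfg.smile_burst_amp * rng.uniform(0.7, 1.0)
                events[other].append((center + lag, amp, "response"))

    series = []
    for m in range(2):
        values = np.zeros(n)
        for center, amp, _kind in events[m]:
            _add_bump(values, cfg.smile_rate_hz, center, amp, cfg.smile_burst_width_s)
        np.clip(values, 0.0, 100.0, out=values)
        series.append(
            SignalSeries(
                participant_id=f"m{m}",
                round=1,
                modality="smile",
                rate_hz=cfg.smile_rate_hz,
                values=values,
            )
        )
    if return_events:
        return series[0], series[1], events[0], events[1]
    return series[0], series[1]


# ---------------------------------------------------------------------------
# Heart-rate signals


def simulate_hr_dyad(cfg: SimConfig, coupling: float, seed=0):
    """Simulate one dyad's heart-rate pair (bpm).

    HR_i(t) = baseline + arousal_amp * exp(-t/tau) + x_i(t), with x_i an AR(1)
    whose innovations are e_i = sqrt(1-c)*u_i + sqrt(c)*s for member-specific
    u_i and shared s (all white with SD ``hr_noise_sd``). x is initialized
    from its stationary scaling of the first innovation, so with c = 1 the two
    members' fluctuation components coincide exactly.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValueError(f"coupling must be in [0, 1], got {coupling}")
    if abs(cfg.hr_ar_coef) >= 1:
        raise ValueError(f"hr_ar_coef implies a non-stationary AR(1): {cfg.hr_ar_coef}")
    rng = as_generator(seed)
    n = cfg.n_samples("hr")
    t = np.arange(n) / cfg.hr_rate_hz
    trend = cfg.hr_baseline_bpm + cfg.hr_arousal_amp_bpm * np.exp(-t / cfg.hr_decay_tau_s)

    phi = cfg.hr_ar_coef
    sd = cfg.hr_noise_sd
    shared = rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)
    own = rng.normal(0.0, sd, (2, n)) if sd > 0 else np.zeros((2, n))
    innov = np.sqrt(1.0 - coupling) * own + np.sqrt(coupling) * shared

    x = np.empty((2, n))
    x[:, 0] = innov[:, 0] / np.sqrt(1.0 - phi**2)
    for i in range(1, n):
        x[:, i] = phi * x[:, i - 1] + innov[:, i]

    series = []
    for m in range(2):
        values = np.maximum(trend + x[m], 1.0)  # HR is strictly positive
        series.append(
            SignalSeries(
                participant_id=f"m{m}",
                round=1,
                modality="hr",
                rate_hz=cfg.hr_rate_hz,
                values=values,
            )
        )
    return series[0], series[1]


# ---------------------------------------------------------------------------
# Outcomes


def _clip_measure(values: np.ndarray, measure: str) -> np.ndarray:
    lo, hi, _mu, _sd, integer, _has_pre = MEASURES[measure]
    out = np.clip(values, lo, hi)
    if integer:
        out = np.copysign(np.floor(np.abs(out) + 0.5), out)
        out = np.clip(out, lo, hi)
    return out


def simulate_outcomes(
    roster: pd.DataFrame,
    truth: pd.DataFrame,
    cfg: SimConfig,
    seed=0,
) -> pd.DataFrame:
    """Pre/post ratings and dictator allocations for every rater x round.

    post = pre + (condition_effect + outcome_effect * (coupling - mean
    coupling) + noise) * pre_sd, clipped to the measure's range (integer
    measures are additionally rounded). Post-only measures (dictator
    allocation, emotion sliders) are generated analogously around their own
    baseline mean. ``truth`` must hold one ``coupling`` value per real dyad.
    """
    rng = as_generator(seed)
    coupling = truth.set_index("dyad_id")["coupling"]
    missing = set(roster["dyad_id"]) - set(coupling.index)
    if missing:
        raise ValueError(f"truth lacks coupling for dyads: {sorted(missing)[:5]} ...")
    c_mean = float(coupling.loc[list(dict.fromkeys(roster["dyad_id"]))].mean())

    rows = []
    for row in roster.itertuples(index=False):
        c_dev = float(coupling[row.dyad_id]) - c_mean
        shift = cfg.condition_effects.get(row.condition, 0.0)
        for rater, partner, fam in (
            (row.member_a, row.member_b, row.familiarity_a),
            (row.member_b, row.member_a, row.familiarity_b),
        ):
            for measure in cfg.measures:
                lo, hi, mu, sd, integer, has_pre = MEASURES[measure]
                effect = shift + cfg.outcome_effect * c_dev + rng.normal(0.0, cfg.outcome_noise_sd)
                if has_pre:
                    pre = float(_clip_measure(np.array([rng.normal(mu, sd)]), measure)[0])
                    post = float(_clip_measure(np.array([pre + effect * sd]), measure)[0])
                else:
                    pre = np.nan
                    post = float(_clip_measure(np.array([rng.normal(mu, sd) + effect * sd]), measure)[0])
                rows.append(
                    {
                        "rater": rater,
                        "partner": partner,
                        "dyad_id": row.dyad_id,
                        "session": row.session,
                        "round": row.round,
                        "condition": row.condition,
                        "familiarity": fam,
                        "measure": measure,
                        "pre": pre,
                        "post": post,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Whole study


def simulate_study(cfg: SimConfig) -> StudyBundle:
    """Simulate a complete study: roster, coupled signals, outcomes, truth.

    Per dyad one latent factor z ~ N(0, 1) shifts both the smile mimicry
    probability and the HR shared-innovation weight around their population
    means (``mimicry_prob``, ``hr_coupling``) by ``coupling_sd * z``, clipped
    to [0, 1]; the outcome-driving latent coupling is the mean of the
    modality couplings in play. Byte-identical rerun under the same config.
    """
    roster = make_roster(
        cfg.n_participants,
        cfg.n_rounds,
        cfg.conditions,
        seed=substream(cfg.seed, "roster"),
        allow_repeats=cfg.allow_repeats,
        familiar_prob=cfg.familiar_prob,
    )

    trait_rng = substream(cfg.seed, "traits")
    nonsmiler_trait = {
        p: bool(trait_rng.random() < cfg.nonsmiler_prob) for p in roster_participants(roster)
    }

    truth_rows = []
    for row in roster.itertuples(index=False):
        z = float(substream(cfg.seed, "coupling", row.dyad_id).normal())
        c_smile = float(np.clip(cfg.mimicry_prob + cfg.coupling_sd * z, 0.0, 1.0))
        c_hr = float(np.clip(cfg.hr_coupling + cfg.coupling_sd * z, 0.0, 1.0))
        parts = [c for m, c in (("smile", c_smile), ("hr", c_hr)) if m in cfg.modalities]
        truth_rows.append(
            {
                "dyad_id": row.dyad_id,
                "condition": row.condition,
                "latent_z": z,
                "coupling_smile": c_smile,
                "coupling_hr": c_hr,
                "coupling": float(np.mean(parts)),
            }
        )
    truth = pd.DataFrame(truth_rows)
    truth_idx = truth.set_index("dyad_id")

    signals: dict[tuple[str, int, str], SignalSeries] = {}
    for row in roster.itertuples(index=False):
        members = (row.member_a, row.member_b)
        if "smile" in cfg.modalities:
            a, b = simulate_smile_dyad(
                cfg,
                float(truth_idx.loc[row.dyad_id, "coupling_smile"]),
                seed=substream(cfg.seed, "smile", row.dyad_id),
                nonsmiler=(nonsmiler_trait[members[0]], nonsmiler_trait[members[1]]),
            )
            for member, s in zip(members, (a, b)):
                signals[(member, row.round, "smile")] = s.replace(
                    participant_id=member,
                    round=row.round,
                    dyad_id=row.dyad_id,
                    condition=row.condition,
                )
        if "hr" in cfg.modalities:
            a, b = simulate_hr_dyad(
                cfg,
                float(truth_idx.loc[row.dyad_id, "coupling_hr"]),
                seed=substream(cfg.seed, "hr", row.dyad_id),
            )
            for member, s in zip(members, (a, b)):
                signals[(member, row.round, "hr")] = s.replace(
                    participant_id=member,
                    round=row.round,
                    dyad_id=row.dyad_id,
                    condition=row.condition,
                )

    ratings = simulate_outcomes(roster, truth, cfg, seed=substream(cfg.seed, "outcomes"))
    return StudyBundle(roster=roster, signals=signals, ratings=ratings, truth=truth, config=cfg)
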