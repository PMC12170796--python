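"""Pseudo-pair null construction.

Pseudo pairs are two participants from the same condition who never (or, for
the round-matched scope, not in that round) actually interacted. Correlating
their recordings gives an empirical null capturing task- and
environment-driven similarity; real-pair synchrony is compared against it.

Two scopes:

* ``any`` — every same-condition participant pair that was never a real
  dyad, with every combination of their per-round recordings (used for the
  smile study, where recordings are comparable across rounds);
* ``round_matched`` — within each round, every same-condition pair not
  actually paired in that round (used for the HR study, where the shared
  session timing matters).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import as_generator
from .prep import prewhiten_ar, round_to_integers, smooth_rolling_mean
from .synchrony import global_synchrony, smile_eligibility
from .synthdata import StudyBundle

__all__ = ["enumerate_pseudo_pairs", "synchrony_table", "validate_roster", "familiar_participants"]

ROSTER_COLUMNS = [
    "session",
    "round",
    "dyad_id",
    "member_a",
    "member_b",
    "condition",
    "familiarity_a",
    "familiarity_b",
    "pair_type",
]


def validate_roster(roster: pd.DataFrame) -> None:
    missing = [c for c in ROSTER_COLUMNS if c not in roster.columns]
    if missing:
        raise ValueError(f"roster is missing columns: {missing}")
    if (roster["member_a"] == roster["member_b"]).any():
        raise ValueError("roster contains a self-paired dyad")


def _real_partner_sets(roster: pd.DataFrame):
    ever = set()
    per_round: dict[int, set] = {}
    for row in roster.itertuples(index=False):
        pair = frozenset((row.member_a, row.member_b))
        ever.add(pair)
        per_round.setdefault(int(row.round), set()).add(pair)
    return ever, per_round


def enumerate_pseudo_pairs(
    roster: pd.DataFrame,
    condition: str,
    scope: str = "any",
    within_session_only: bool = False,
) -> pd.DataFrame:
    """All pseudo pairings for one condition.

    Returns one row per *recording* pairing: (member_a, round_a) with
    (member_b, round_b). Under ``any``, partners that ever met are excluded
    and all round combinations of the remaining pairs are enumerated; under
    ``round_matched`` only same-round combinations of participants not paired
    in that round are produced.
    """
    validate_roster(roster)
    if condition not in set(roster["condition"]):
        raise ValueError(f"unknown condition {condition!r}")
    if scope not in ("any", "round_matched"):
        raise ValueError(f"scope must be 'any' or 'round_matched', got {scope!r}")
    df = roster[(roster["condition"] == condition) & (roster["pair_type"] == "real")]
    ever, per_round = _real_partner_sets(df)

    rounds_of: dict[str, list[int]] = {}
    session_of: dict[str, int] = {}
    for row in df.itertuples(index=False):
        for m in (row.member_a, row.member_b):
            rounds_of.setdefault(m, []).append(int(row.round))
            session_of[m] = int(row.session)
    participants = sorted(rounds_of)
    for m in participants:
        rounds_of[m] = sorted(set(rounds_of[m]))

    rows = []
    if scope == "any":
        for i, p in enumerate(participants):
            for q in participants[i + 1 :]:
                if frozenset((p, q)) in ever:
                    continue
                if within_session_only and session_of[p] != session_of[q]:
                    continue
                for ra in rounds_of[p]:
                    for rb in rounds_of[q]:
                        rows.append((p, ra, q, rb))
    else:
        for r, paired in sorted(per_round.items()):
            present = sorted({m for pair in paired for m in pair})
            for i, p in enumerate(present):
                for q in present[i + 1 :]:
                    if frozenset((p, q)) in paired:
                        continue
                    if within_session_only and session_of[p] != session_of[q]:
                        continue
                    rows.append((p, r, q, r))
    out = pd.DataFrame(rows, columns=["member_a", "round_a", "member_b", "round_b"])
    out["condition"] = condition
    out["pair_type"] = "pseudo"
    out["pair_id"] = [
        f"pseudo:{a}@r{ra}|{b}@r{rb}"
        for a, ra, b, rb in zip(out["member_a"], out["round_a"], out["member_b"], out["round_b"])
    ]
    return out


def familiar_participants(roster: pd.DataFrame) -> set[str]:
    """Participants who reported any prior familiarity with a real partner."""
    out: set[str] = set()
    for row in roster.itertuples(index=False):
        if row.familiarity_a > 0 or row.familiarity_b > 0:
            out.update((row.member_a, row.member_b))
    return out


def _preprocess_cache(bundle: StudyBundle, modality: str, smooth_window: int, max_order):
    """Preprocess each recording once; returns {(participant, round): (raw, proc)}."""
    cache = {}
    for (participant, rnd, mod), series in bundle.signals.items():
        if mod != modality:
            continue
        if modality == "smile":
            proc = smooth_rolling_mean(round_to_integers(series), smooth_window)
        else:
            proc, _fit = prewhiten_ar(series, max_order=max_order)
        cache[(participant, rnd)] = (series, proc)
    return cache


def synchrony_table(
    bundle: StudyBundle,
    modality: str = "smile",
    method: str = "pearson",
    scope: str | None = None,
    smooth_window: int = 4,
    prewhiten_max_order: int | None = None,
    pseudo_cap: int | None = None,
    exclude_familiar: bool = False,
    within_session_only: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """One synchrony record per real dyad and per pseudo pairing.

    Smile recordings are rounded + smoothed and filtered by the
    both-members-smiled eligibility rule (checked on the raw series); HR
    recordings are prewhitened and their residual tails aligned to a common
    length. ``scope`` defaults to ``any`` for smile and ``round_matched`` for
    HR. ``pseudo_cap`` subsamples pseudo pairings per condition (seeded) when
    full enumeration is unnecessary. Missing recordings are skipped and
    counted in the ``n_missing`` attribute of the returned frame.
    """
    if modality not in ("smile", "hr"):
        raise ValueError(f"modality must be 'smile' or 'hr', got {modality!r}")
    if scope is None:
        scope = "any" if modality == "smile" else "round_matched"
    roster = bundle.roster
    validate_roster(roster)
    cache = _preprocess_cache(bundle, modality, smooth_window, prewhiten_max_order)

    banned: set[str] = familiar_participants(roster) if exclude_familiar else set()

    pairings = []
    for row in roster[roster["pair_type"] == "real"].itertuples(index=False):
        pairings.append(
            {
                "pair_id": row.dyad_id,
                "member_a": row.member_a,
                "round_a": int(row.round),
                "member_b": row.member_b,
                "round_b": int(row.round),
                "condition": row.condition,
                "pair_type": "real",
            }
        )
    rng = as_generator(seed)
    for condition in dict.fromkeys(roster["condition"]):
        pseudo = enumerate_pseudo_pairs(
            roster, condition, scope=scope, within_session_only=within_session_only
        )
        if pseudo_cap is not None and len(pseudo) > pseudo_cap:
            keep = np.sort(rng.choice(len(pseudo), size=pseudo_cap, replace=False))
            pseudo = pseudo.iloc[keep]
        pairings.extend(pseudo.to_dict("records"))

    records = []
    n_missing = 0
    for p in pairings:
        if p["member_a"] in banned or p["member_b"] in banned:
            continue
        key_a = (p["member_a"], p["round_a"])
        key_b = (p["member_b"], p["round_b"])
        if key_a not in cache or key_b not in cache:
            n_missing += 1
            continue
        raw_a, proc_a = cache[key_a]
        raw_b, proc_b = cache[key_b]
        mean_a = float(np.mean(raw_a.values))
        mean_b = float(np.mean(raw_b.values))
        if modality == "smile":
            eligible, reason = smile_eligibility(raw_a, raw_b)
            if not eligible:
                records.append(
                    {
                        "pair_id": p["pair_id"],
                        "condition": p["condition"],
                        "pair_type": p["pair_type"],
                        "method": method,
                        "prewhitened": False,
                        "r": np.nan,
                        "mean_a": mean_a,
                        "mean_b": mean_b,
                        "mean_pair": (mean_a + mean_b) / 2.0,
                        "n_samples": raw_a.n_samples,
                        "eligible": False,
                        "exclusion_reason": reason,
                    }
                )
                continue
            a, b = proc_a, proc_b
            prewhitened = False
        else:
            # residual lengths differ with AR order; align the tails
            n = min(proc_a.n_samples, proc_b.n_samples)
            a = proc_a.replace(values=proc_a.values[-n:])
            b = proc_b.replace(values=proc_b.values[-n:])
            prewhitened = True
        rec = global_synchrony(
            a,
            b,
            method=method,
            prewhitened=prewhitened,
            pair_id=p["pair_id"],
            pair_type=p["pair_type"],
            mean_a=mean_a,
            mean_b=mean_b,
        )
        d = rec.to_dict()
        d["condition"] = p["condition"]
        records.append(d)

    columns = [
        "pair_id",
        "condition",
        "pair_type",
        "method",
        "prewhitened",
        "r",
        "mean_a",
        "mean_b",
        "mean_pair",
        "n_samples",
        "eligible",
        "exclusion_reason",
    ]
    table = pd.DataFrame(records, columns=columns)
    table.attrs["n_missing"] = n_missing
    table.attrs["scope"] = scope
    table.attrs["modality"] = modality
    return table
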