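"""CSV/JSON round-tripping of study bundles.

A study directory holds ``roster.csv``, ``ratings.csv`` (long format),
``signals.csv`` (long format: participant, round, modality, rate_hz,
time_s, value) and ``truth.json`` (per-dyad latent couplings plus the
generator configuration). Reading validates schemas and value ranges and
reports the offending file, row and column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .pseudonull import ROSTER_COLUMNS, validate_roster
from .series import SignalSeries
from .synthdata import MEASURES, SimConfig, StudyBundle

__all__ = ["write_study", "read_study", "SchemaError"]

RATINGS_COLUMNS = [
    "rater",
    "partner",
    "dyad_id",
    "session",
    "round",
    "condition",
    "familiarity",
    "measure",
    "pre",
    "post",
]
SIGNALS_COLUMNS = [
    "participant",
    "round",
    "modality",
    "rate_hz",
    "dyad_id",
    "condition",
    "time_s",
    "value",
]


class SchemaError(ValueError):
    """Malformed study file: carries file, row and column context."""


def _require_columns(df: pd.DataFrame, cols: list[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def _check(condition: pd.Series, path: Path, column: str, message: str) -> None:
    bad = ~condition
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(f"{path}, row {row + 2}, column {column!r}: {message}")


def write_study(bundle: StudyBundle, directory) -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "roster": directory / "roster.csv",
        "ratings": directory / "ratings.csv",
        "signals": directory / "signals.csv",
        "truth": directory / "truth.json",
    }
    bundle.roster.to_csv(paths["roster"], index=False)
    # %.17g preserves doubles exactly through the CSV round trip
    bundle.ratings.to_csv(paths["ratings"], index=False, float_format="%.17g")

    frames = []
    for (participant, rnd, modality), s in sorted(bundle.signals.items()):
        frames.append(
            pd.DataFrame(
                {
                    "participant": participant,
                    "round": rnd,
                    "modality": modality,
                    "rate_hz": s.rate_hz,
                    "dyad_id": s.dyad_id,
                    "condition": s.condition,
                    "time_s": s.times,
                    "value": s.values,
                }
            )
        )
    signals = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=SIGNALS_COLUMNS)
    )
    signals.to_csv(paths["signals"], index=False, float_format="%.17g")

    payload = {
        "truth": bundle.truth.to_dict(orient="list"),
        "config": bundle.config.to_dict(),
    }
    paths["truth"].write_text(json.dumps(payload, indent=1))
    return paths


def read_study(directory) -> StudyBundle:
    directory = Path(directory)
    roster_path = directory / "roster.csv"
    ratings_path = directory / "ratings.csv"
    signals_path = directory / "signals.csv"
    truth_path = directory / "truth.json"
    for p in (roster_path, ratings_path, signals_path, truth_path):
        if not p.exists():
            raise FileNotFoundError(f"study directory is missing {p.name}")

    roster = pd.read_csv(roster_path)
    _require_columns(roster, ROSTER_COLUMNS, roster_path)
    validate_roster(roster)

    ratings = pd.read_csv(ratings_path, float_precision="round_trip")
    _require_columns(ratings, RATINGS_COLUMNS, ratings_path)
    known = ratings["measure"].isin(MEASURES)
    _check(known, ratings_path, "measure", "unknown measure label")
    for measure, (lo, hi, *_rest) in MEASURES.items():
        mask = ratings["measure"] == measure
        if not mask.any():
            continue
        post = ratings.loc[mask, "post"]
        ok = post.isna() | ((post >= lo) & (post <= hi))
        _check(
            ok.reindex(ratings.index, fill_value=True),
            ratings_path,
            "post",
            f"{measure} outside [{lo}, {hi}]",
        )

    signals_df = pd.read_csv(signals_path, float_precision="round_trip")
    _require_columns(signals_df, SIGNALS_COLUMNS, signals_path)
    if len(signals_df):
        _check(signals_df["modality"].isin(["smile", "hr"]), signals_path, "modality", "unknown modality")
        _check(signals_df["value"].notna(), signals_path, "value", "missing sample value")
        smile = signals_df["modality"] == "smile"
        _check(
            (~smile) | ((signals_df["value"] >= 0) & (signals_df["value"] <= 100)),
            signals_path,
            "value",
            "smile intensity outside [0, 100]",
        )
        _check(
            smile | (signals_df["value"] > 0),
            signals_path,
            "value",
            "heart rate must be positive",
        )

    payload = json.loads(truth_path.read_text())
    config = SimConfig.from_dict(payload["config"])
    truth = pd.DataFrame(payload["truth"])

    signals: dict[tuple[str, int, str], SignalSeries] = {}
    if len(signals_df):
        for (participant, rnd, modality), g in signals_df.groupby(
            ["participant", "round", "modality"], sort=True
        ):
            g = g.sort_values("time_s")
            dyad = g["dyad_id"].iloc[0]
            cond = g["condition"].iloc[0]
            signals[(participant, int(rnd), modality)] = SignalSeries(
                participant_id=str(participant),
                round=int(rnd),
                modality=str(modality),
                rate_hz=float(g["rate_hz"].iloc[0]),
                values=g["value"].to_numpy(dtype=float),
                dyad_id=None if pd.isna(dyad) else str(dyad),
                condition=None if pd.isna(cond) else str(cond),
            )
    return StudyBundle(roster=roster, signals=signals, ratings=ratings, truth=truth, config=config)
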