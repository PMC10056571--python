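"""The r'-wave algorithm: a four-criterion composite score.

Each of the four criteria retained for the composite (the apex angle β, the
downslope angle α, and the triangle-base durations DBT-5mm and DBT-iso)
contributes one point when the patient's major value reaches its cut-off:

    β ≥ 40°,  α ≥ 24°,  DBT-5mm ≥ 120 ms,  DBT-iso ≥ 80 ms

(all comparisons inclusive). The score is the unweighted count, 0–4, and a
patient is predicted to have a positive provocation test when the score
reaches the decision cut-off, 2 by default. Patients without a measurable
r'-wave default to a negative prediction — the absence of a measurable
terminal deflection is itself evidence against the Brugada pattern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ScoreConfig", "RWaveScore", "score_patient", "score_cohort"]

_SCORED = ("beta_deg", "alpha_deg", "dbt5_ms", "dbtiso_ms")


@dataclass(frozen=True)
class ScoreConfig:
    """Cut-offs of the r'-wave algorithm (all inclusive, ≥)."""

    beta_cut_deg: float = 40.0
    alpha_cut_deg: float = 24.0
    dbt5_cut_ms: float = 120.0
    dbtiso_cut_ms: float = 80.0
    score_cut: int = 2

    def __post_init__(self) -> None:
        for name in ("beta_cut_deg", "alpha_cut_deg", "dbt5_cut_ms", "dbtiso_cut_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.score_cut not in (1, 2, 3, 4):
            raise ValueError("score_cut must be in 1..4")

    @classmethod
    def from_dict(cls, data: dict) -> "ScoreConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown ScoreConfig fields: {sorted(unknown)}")
        return cls(**data)

    @property
    def cuts(self) -> dict[str, float]:
        return {
            "beta_deg": self.beta_cut_deg,
            "alpha_deg": self.alpha_cut_deg,
            "dbt5_ms": self.dbt5_cut_ms,
            "dbtiso_ms": self.dbtiso_cut_ms,
        }


@dataclass
class RWaveScore:
    """Result of scoring one patient."""

    beta_pos: bool
    alpha_pos: bool
    dbt5_pos: bool
    dbtiso_pos: bool
    score: int
    prediction: str  # "positive" | "negative"
    basis: str  # "measured" | "unmeasurable_default"
    notes: str = ""

    def __post_init__(self) -> None:
        flags = [self.beta_pos, self.alpha_pos, self.dbt5_pos, self.dbtiso_pos]
        if self.score != sum(flags):
            raise ValueError("score must equal the number of positive criteria")


def _flag(value: float | None, cut: float) -> tuple[bool, bool]:
    """Return (flag, was_missing) applying the inclusive cut."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False, True
    return bool(value >= cut), False


def score_patient(features, config: ScoreConfig = ScoreConfig()) -> RWaveScore:
    """Score one patient.

    ``features`` is a :class:`rprime.geometry.PatientFeatures` or any object
    or mapping exposing ``beta_deg``, ``alpha_deg``, ``dbt5_ms``,
    ``dbtiso_ms`` and ``any_measurable``. Missing individual criteria score
    no point and are recorded in ``notes``; a fully unmeasurable patient is
    scored 0 with ``basis="unmeasurable_default"`` and predicted negative.
    """
    get = features.get if hasattr(features, "get") else lambda k, d=None: getattr(features, k, d)
    if not get("any_measurable", False):
        return RWaveScore(False, False, False, False, 0, "negative", "unmeasurable_default")
    flags: dict[str, bool] = {}
    missing: list[str] = []
    for crit, cut in config.cuts.items():
        flags[crit], was_missing = _flag(get(crit), cut)
        if was_missing:
            missing.append(crit)
    score = sum(flags.values())
    return RWaveScore(
        beta_pos=flags["beta_deg"],
        alpha_pos=flags["alpha_deg"],
        dbt5_pos=flags["dbt5_ms"],
        dbtiso_pos=flags["dbtiso_ms"],
        score=score,
        prediction="positive" if score >= config.score_cut else "negative",
        basis="measured",
        notes=("missing: " + ",".join(missing)) if missing else "",
    )


def score_cohort(
    features: pd.DataFrame, config: ScoreConfig = ScoreConfig()
) -> pd.DataFrame:
    """Score every patient of a feature table.

    Expects the standard feature-table columns (``rprime.io.FEATURE_COLUMNS``
    or at least the four criterion columns plus the measurability flags).
    Returns the input with flag/score/prediction/basis columns appended; the
    integer ``score`` column is the continuous marker used when the
    algorithm itself enters a ROC analysis.
    """
    if len(features) == 0:
        raise ValueError("empty feature table")
    out = features.copy()
    meas_cols = [c for c in ("measurable_ii", "measurable_iii", "measurable_iv") if c in out]
    if "any_measurable" in out.columns:
        any_meas = out["any_measurable"].astype(bool)
    elif meas_cols:
        any_meas = out[meas_cols].astype(bool).any(axis=1)
    else:
        any_meas = out[list(_SCORED)].notna().any(axis=1)

    results = []
    for i, row in out.iterrows():
        payload = {c: row.get(c) for c in _SCORED}
        payload["any_measurable"] = bool(any_meas.loc[i])
        results.append(score_patient(payload, config))
    out["beta_pos"] = [r.beta_pos for r in results]
    out["alpha_pos"] = [r.alpha_pos for r in results]
    out["dbt5_pos"] = [r.dbt5_pos for r in results]
    out["dbtiso_pos"] = [r.dbtiso_pos for r in results]
    out["score"] = np.array([r.score for r in results], dtype=int)
    out["prediction"] = [r.prediction for r in results]
    out["basis"] = [r.basis for r in results]
    return out
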