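"""Arousal-based individual screening (AIS) and composite behavioral scores.

Stressed mice are segregated into susceptible and resilient phenotypes by
z-normalizing their post-stress ASR changes (% of baseline, sessions at
days 14 and 28) against a reference population and thresholding the
resulting arousal score at >= 1 (inclusive). Additional composites are
built from the post-segregation behavioral tests: an avoidance-like score
(open field + elevated plus maze), a social-memory score, and an overall
PTSD-like score (mean of the three domain scores). Every measure is
sign-oriented so that larger scores are more PTSD-like.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .synthetic_cohort import MouseRecord, records_to_frame

SCORE_COLUMNS = ("arousal_score", "avoidance_score", "social_memory_score",
                 "ptsd_like_score")


class SegregationError(ValueError):
    """Invalid input to the scoring/segregation layer."""


@dataclass(frozen=True)
class SegregationConfig:
    threshold: float = 1.0
    #: population whose mean/SD define the z-scale: controls | stressed | all
    reference_population: str = "controls"
    #: how the two ASR sessions combine: mean_of_z | z_of_mean
    session_aggregation: str = "mean_of_z"
    #: sign per raw behavioral measure so that larger oriented value = more
    #: PTSD-like (raw units here have lower = more PTSD-like, hence -1)
    score_orientation: Mapping[str, float] = field(
        default_factory=lambda: {"of_measure": -1.0, "epm_measure": -1.0,
                                 "sm_measure": -1.0}
    )

    def validate(self) -> None:
        if not np.isfinite(self.threshold):
            raise SegregationError("threshold must be finite")
        if self.reference_population not in ("controls", "stressed", "all"):
            raise SegregationError(
                f"unknown reference_population {self.reference_population!r}"
            )
        if self.session_aggregation not in ("mean_of_z", "z_of_mean"):
            raise SegregationError(
                f"unknown session_aggregation {self.session_aggregation!r}"
            )


def zscore(values, reference) -> np.ndarray:
    """Z-normalize ``values`` against the mean/SD (ddof=1) of ``reference``."""
    values = np.asarray(values, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if reference.size < 2:
        raise SegregationError("reference population needs >= 2 values")
    sd = reference.std(ddof=1)
    if sd == 0:
        raise SegregationError("reference population has zero standard deviation")
    return (values - reference.mean()) / sd


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(list(records))


def _reference_mask(frame: pd.DataFrame, population: str) -> pd.Series:
    if population == "controls":
        return frame["group"] == "control"
    if population == "stressed":
        return frame["group"] == "stressed"
    return pd.Series(True, index=frame.index)


def arousal_score(records, config: SegregationConfig | None = None) -> pd.Series:
    """Per-mouse arousal score from the two post-stress ASR sessions.

    Each session's % change is z-normalized against the reference
    population's values for the same session; the two sessions are then
    combined per ``session_aggregation``.
    """
    config = config or SegregationConfig()
    config.validate()
    frame = _as_frame(records)
    for col in ("asr1_pct", "asr2_pct"):
        bad = frame[~np.isfinite(frame[col].astype(float))]
        if len(bad):
            raise SegregationError(
                f"missing/non-finite {col} for mouse {bad.iloc[0]['mouse_id']}"
            )
    ref = frame[_reference_mask(frame, config.reference_population)]
    if config.session_aggregation == "mean_of_z":
        z1 = zscore(frame["asr1_pct"], ref["asr1_pct"])
        z2 = zscore(frame["asr2_pct"], ref["asr2_pct"])
        score = (z1 + z2) / 2.0
    else:  # z_of_mean
        mean_all = (frame["asr1_pct"].astype(float)
                    + frame["asr2_pct"].astype(float)) / 2.0
        mean_ref = (ref["asr1_pct"].astype(float)
                    + ref["asr2_pct"].astype(float)) / 2.0
        score = zscore(mean_all, mean_ref)
    return pd.Series(np.asarray(score), index=frame["mouse_id"].to_numpy(),
                     name="arousal_score")


def segregate(scores: pd.Series, groups: pd.Series,
              threshold: float = 1.0) -> tuple[pd.Series, dict[str, int]]:
    """Assign phenotype labels from arousal scores.

    Stressed mice with score >= ``threshold`` (inclusive) are susceptible,
    the rest resilient; control mice keep the ``control`` label. Returns
    the labels and the label counts.
    """
    scores = pd.Series(scores)
    if not np.all(np.isfinite(scores.to_numpy(dtype=float))):
        raise SegregationError("arousal scores must be finite")
    groups = pd.Series(groups)
    labels = pd.Series("control", index=scores.index, name="phenotype")
    stressed = groups.to_numpy() == "stressed"
    labels[stressed & (scores.to_numpy() >= threshold)] = "susceptible"
    labels[stressed & (scores.to_numpy() < threshold)] = "resilient"
    counts = labels.value_counts().to_dict()
    for key in ("control", "susceptible", "resilient"):
        counts.setdefault(key, 0)
    return labels, counts


def composite_scores(records, config: SegregationConfig | None = None) -> pd.DataFrame:
    """Full behavioral scoring table.

    Columns: mouse_id, the four scores (arousal, avoidance-like,
    social-memory, PTSD-like) and the phenotype label. The avoidance-like
    score is the mean oriented z of open-field and elevated-plus-maze
    measures, social memory the oriented z of the 5-trial social-memory
    measure, and the PTSD-like score the mean of the three domain scores.
    """
    config = config or SegregationConfig()
    config.validate()
    frame = _as_frame(records)
    for measure in ("of_measure", "epm_measure", "sm_measure"):
        if measure not in config.score_orientation:
            raise SegregationError(f"orientation map lacks {measure}")
        if frame[measure].astype(float).isna().any():
            raise SegregationError(f"missing {measure} values")
    ref = frame[_reference_mask(frame, config.reference_population)]

    arousal = arousal_score(frame, config)
    oriented = {}
    for measure, sign in config.score_orientation.items():
        oriented[measure] = sign * np.asarray(
            zscore(frame[measure], ref[measure])
        )
    avoidance = (oriented["of_measure"] + oriented["epm_measure"]) / 2.0
    social = oriented["sm_measure"]
    ptsd_like = (arousal.to_numpy() + avoidance + social) / 3.0

    labels, _ = segregate(arousal,
                          pd.Series(frame["group"].to_numpy(),
                                    index=arousal.index),
                          config.threshold)
    out = pd.DataFrame(
        {
            "mouse_id": frame["mouse_id"].to_numpy(),
            "arousal_score": arousal.to_numpy(),
            "avoidance_score": avoidance,
            "social_memory_score": social,
            "ptsd_like_score": ptsd_like,
            "phenotype": labels.to_numpy(),
        }
    )
    if not np.all(np.isfinite(out[list(SCORE_COLUMNS)].to_numpy())):
        raise SegregationError("non-finite composite score produced")
    return out
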