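"""Trial-level data schema, CSV round-trips, and aggregation to response-count tables.

The canonical in-memory container for a set of trials is a pandas
:class:`~pandas.DataFrame` with the columns of :data:`TRIAL_COLUMNS`.  A
:class:`Trial` dataclass is provided for row-level construction and
validation; ``trials_to_frame`` / ``frame_to_trials`` convert between the
two representations losslessly.

Schema
------
participant_id : str
    Opaque participant identifier.
ethnicity : str or missing
    Optional participant-level covariate, one of ``{"white", "east_asian"}``;
    must be constant within a participant.
condition : str
    Visual condition, one of ``{"direct_gaze", "eyes_closed", "baseline"}``.
    Empty on vigilance rows.
trial_type : str
    ``{"experimental", "vigilance_auditory", "vigilance_visual"}``.
azimuth_deg : float
    Signed azimuth of the simulated sound source; negative = listener's
    left.  Experimental trials use the 9-point grid −40°..+40° in 10°
    steps.  Empty on vigilance rows.
response : str
    3AFC response, one of ``{"left", "middle", "right"}``.  Empty on
    vigilance rows (catch-trial keypresses are not spatial judgments).
vigilance_correct : bool
    Present iff the row is a vigilance trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRIAL_COLUMNS = [
    "participant_id",
    "ethnicity",
    "condition",
    "trial_type",
    "azimuth_deg",
    "response",
    "vigilance_correct",
]

CONDITIONS = ("direct_gaze", "eyes_closed", "baseline")
RESPONSES = ("left", "middle", "right")
TRIAL_TYPES = ("experimental", "vigilance_auditory", "vigilance_visual")
ETHNICITIES = ("white", "east_asian")

#: The 9 azimuths of the experimental design, degrees.
DESIGN_AZIMUTHS = np.arange(-40.0, 50.0, 10.0)

#: The two easiest locations, used by the edge-accuracy QC rule.
EDGE_AZIMUTHS = (-40.0, 40.0)


class SchemaError(ValueError):
    """Raised when a trial table violates the schema or its invariants."""


@dataclass(frozen=True)
class Trial:
    """One behavioral response at one azimuth under one condition."""

    participant_id: str
    condition: Optional[str]
    azimuth_deg: Optional[float]
    response: Optional[str]
    trial_type: str = "experimental"
    vigilance_correct: Optional[bool] = None
    ethnicity: Optional[str] = None

    def __post_init__(self) -> None:
        if self.trial_type not in TRIAL_TYPES:
            raise SchemaError(f"unknown trial_type {self.trial_type!r}")
        if self.trial_type == "experimental":
            if self.vigilance_correct is not None:
                raise SchemaError("experimental trial carries vigilance_correct")
            if self.condition not in CONDITIONS:
                raise SchemaError(f"unknown condition {self.condition!r}")
            if self.response not in RESPONSES:
                raise SchemaError(f"unknown response {self.response!r}")
            if self.azimuth_deg is None or float(self.azimuth_deg) not in DESIGN_AZIMUTHS:
                raise SchemaError(
                    f"experimental azimuth {self.azimuth_deg!r} not on the "
                    "design grid -40..40 in 10 deg steps"
                )
        else:
            if self.vigilance_correct is None:
                raise SchemaError("vigilance trial missing vigilance_correct")
        if self.ethnicity is not None and self.ethnicity not in ETHNICITIES:
            raise SchemaError(f"unknown ethnicity {self.ethnicity!r}")


def trials_to_frame(trials: Iterable[Trial]) -> pd.DataFrame:
    """Convert an iterable of :class:`Trial` into the canonical DataFrame."""
    rows = [
        {
            "participant_id": t.participant_id,
            "ethnicity": t.ethnicity,
            "condition": t.condition,
            "trial_type": t.trial_type,
            "azimuth_deg": t.azimuth_deg,
            "response": t.response,
            "vigilance_correct": t.vigilance_correct,
        }
        for t in trials
    ]
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def frame_to_trials(df: pd.DataFrame) -> list[Trial]:
    """Convert a validated trial DataFrame into a list of :class:`Trial`."""
    out = []
    for row in df.itertuples(index=False):
        out.append(
            Trial(
                participant_id=str(row.participant_id),
                ethnicity=None if pd.isna(row.ethnicity) else str(row.ethnicity),
                condition=None if pd.isna(row.condition) else str(row.condition),
                trial_type=str(row.trial_type),
                azimuth_deg=None if pd.isna(row.azimuth_deg) else float(row.azimuth_deg),
                response=None if pd.isna(row.response) else str(row.response),
                vigilance_correct=None
                if pd.isna(row.vigilance_correct)
                else bool(row.vigilance_correct),
            )
        )
    return out


def _row_violations(df: pd.DataFrame) -> pd.Series:
    """Boolean mask of rows violating Trial invariants, vectorized."""
    exp = df["trial_type"] == "experimental"
    vig = df["trial_type"].isin(("vigilance_auditory", "vigilance_visual"))
    bad_type = ~(exp | vig)

    bad_az = exp & ~df["azimuth_deg"].isin(DESIGN_AZIMUTHS)
    bad_cond = exp & ~df["condition"].isin(CONDITIONS)
    bad_resp = exp & ~df["response"].isin(RESPONSES)
    bad_vc_present = exp & df["vigilance_correct"].notna()
    bad_vc_absent = vig & df["vigilance_correct"].isna()
    bad_eth = df["ethnicity"].notna() & ~df["ethnicity"].isin(ETHNICITIES)
    return bad_type | bad_az | bad_cond | bad_resp | bad_vc_present | bad_vc_absent | bad_eth


def validate_trials(df: pd.DataFrame, strict: bool = True) -> pd.DataFrame:
    """Validate a trial table against the schema invariants.

    In strict mode any violation raises :class:`SchemaError` naming the first
    offending row; in lenient mode offending rows are dropped (and counted in
    the module logger).  Constancy of ethnicity within participant is always
    enforced strictly, since silently dropping rows cannot repair it.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    df = df[TRIAL_COLUMNS].copy()

    bad = _row_violations(df)
    if bad.any():
        if strict:
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(f"row {i} violates trial invariants: {df.iloc[i].to_dict()}")
        logger.warning("dropping %d invalid trial rows (lenient mode)", int(bad.sum()))
        df = df.loc[~bad].reset_index(drop=True)

    eth = df.dropna(subset=["ethnicity"]).groupby("participant_id")["ethnicity"].nunique()
    if (eth > 1).any():
        who = eth.index[eth > 1].tolist()
        raise SchemaError(f"ethnicity not constant within participant(s): {who}")
    return df


def read_trials(path, strict: bool = True) -> pd.DataFrame:
    """Read a trial CSV into the canonical DataFrame.

    Parameters
    ----------
    path : path-like
        CSV with the columns of :data:`TRIAL_COLUMNS` (comma-separated,
        UTF-8, one header row).
    strict : bool
        If True (default), any invariant violation aborts with
        :class:`SchemaError`; otherwise violating rows are dropped and
        counted in the log.
    """
    df = pd.read_csv(
        path,
        dtype={"participant_id": str, "ethnicity": str, "condition": str,
               "trial_type": str, "response": str},
    )
    if "vigilance_correct" in df.columns:
        df["vigilance_correct"] = df["vigilance_correct"].map(
            {True: True, False: False, "True": True, "False": False, 1.0: True, 0.0: False}
        )
    return validate_trials(df, strict=strict)


def write_trials(df: pd.DataFrame, path) -> None:
    """Write a validated trial table as CSV; inverse of :func:`read_trials`."""
    validate_trials(df, strict=True).to_csv(path, index=False)


def aggregate_counts(trials: pd.DataFrame) -> pd.DataFrame:
    """Aggregate experimental trials to per-participant × condition count tables.

    Vigilance trials are filtered out internally.  Returns a tidy frame with
    one row per (participant_id, condition, azimuth_deg) and columns
    ``n_left, n_middle, n_right, n_total``; azimuths of the design grid with
    no trials appear as zero-count rows so downstream code can detect
    incomplete designs.  Invariant under trial reordering.
    """
    exp = trials[trials["trial_type"] == "experimental"]
    if exp.empty:
        return pd.DataFrame(
            columns=["participant_id", "condition", "azimuth_deg",
                     "n_left", "n_middle", "n_right", "n_total"]
        )
    ct = (
        exp.groupby(["participant_id", "condition", "azimuth_deg"])["response"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(RESPONSES), fill_value=0)
    )
    # complete the design grid with zero-count rows per participant-condition
    pc = exp[["participant_id", "condition"]].drop_duplicates()
    full_index = pd.MultiIndex.from_frame(
        pc.merge(pd.DataFrame({"azimuth_deg": DESIGN_AZIMUTHS}), how="cross")
    )
    ct = ct.reindex(full_index, fill_value=0)
    out = ct.rename(columns={"left": "n_left", "middle": "n_middle", "right": "n_right"})
    out["n_total"] = out[["n_left", "n_middle", "n_right"]].sum(axis=1)
    out = out.reset_index().sort_values(
        ["participant_id", "condition", "azimuth_deg"]
    ).reset_index(drop=True)
    out.columns.name = None
    return out


@dataclass
class ResponseCountTable:
    """Counts of left/middle/right responses at each azimuth for one
    participant × condition."""

    participant_id: str
    condition: str
    counts: pd.DataFrame  # columns azimuth_deg, n_left, n_middle, n_right, n_total

    def proportions(self) -> pd.DataFrame:
        """Observed response proportions at azimuths with at least one trial."""
        c = self.counts[self.counts["n_total"] > 0].copy()
        for cat in ("left", "middle", "right"):
            c[f"p_{cat}"] = c[f"n_{cat}"] / c["n_total"]
        return c


def iter_count_tables(counts: pd.DataFrame) -> Iterable[ResponseCountTable]:
    """Yield one :class:`ResponseCountTable` per (participant, condition)."""
    for (pid, cond), sub in counts.groupby(["participant_id", "condition"], sort=True):
        yield ResponseCountTable(
            participant_id=str(pid),
            condition=str(cond),
            counts=sub[["azimuth_deg", "n_left", "n_middle", "n_right", "n_total"]]
            .reset_index(drop=True),
        )
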