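"""Participant exclusion rules and the auditable QC report.

Three rules, applied to whole participants:

* **vigilance** — more than 20% of vigilance (catch) trials failed
  (strict inequality; exactly 20% is retained);
* **edge_accuracy** — accuracy below 80% at either of the easiest
  azimuths (−40°, +40°) in any condition (strict; exactly 80% is
  retained).  "Correct" at an edge means reporting the matching side;
  "middle" counts as incorrect;
* **fit_failure** — the joint psychometric fit (or its cone width) failed
  in any condition.  Assessed only for participants passing the first two
  rules, mirroring the sequential exclusion order of the analysis this
  package implements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EDGE_AZIMUTHS, aggregate_counts

__all__ = ["QCConfig", "vigilance_check", "edge_accuracy_check",
           "apply_exclusions"]


class QCDataError(ValueError):
    """Raised when a check's inputs are structurally unusable."""


@dataclass
class QCConfig:
    vigilance_fail_threshold: float = 0.20   # excluded iff fail rate > this
    edge_accuracy_threshold: float = 0.80    # excluded iff accuracy < this
    edge_pooled: bool = False                # pool conditions before the edge rule


def vigilance_check(trials: pd.DataFrame,
                    threshold: float = 0.20) -> pd.DataFrame:
    """Per-participant vigilance fail rate and exclusion flag.

    Flagged iff fail rate is strictly greater than ``threshold``.  Every
    participant must have at least one vigilance trial.
    """
    vig = trials[trials["trial_type"].isin(("vigilance_auditory", "vigilance_visual"))]
    participants = trials["participant_id"].unique()
    missing = set(participants) - set(vig["participant_id"].unique())
    if missing:
        raise QCDataError(f"participants without vigilance trials: {sorted(missing)}")
    g = vig.groupby("participant_id")["vigilance_correct"]
    out = pd.DataFrame({
        "n_vigilance": g.size(),
        "n_failed": g.apply(lambda s: int((~s.astype(bool)).sum())),
    })
    out["vigilance_fail_rate"] = out["n_failed"] / out["n_vigilance"]
    out["vigilance_flag"] = out["vigilance_fail_rate"] > threshold
    return out.reset_index()


def edge_accuracy_check(counts: pd.DataFrame, threshold: float = 0.80,
                        pooled: bool = False) -> pd.DataFrame:
    """Accuracy at the ±40° edges, per participant (× condition).

    At −40° the correct response is "left", at +40° "right"; middle is
    incorrect.  Flagged iff any of the participant's (condition ×) edge
    accuracies is strictly below ``threshold``.  With ``pooled=True``
    counts are summed over conditions before the rule is applied.
    """
    edges = counts[counts["azimuth_deg"].isin(EDGE_AZIMUTHS)].copy()
    if edges.empty or (edges["n_total"] == 0).any():
        raise QCDataError("edge azimuths (-40, +40) missing or empty for some group")
    have = edges.groupby(["participant_id", "condition"])["azimuth_deg"].nunique()
    if (have < 2).any():
        bad = have.index[have < 2].tolist()
        raise QCDataError(f"missing an edge azimuth for: {bad}")

    keys = ["participant_id"] if pooled else ["participant_id", "condition"]
    agg = edges.groupby(keys + ["azimuth_deg"])[["n_left", "n_right", "n_total"]].sum()
    agg = agg.reset_index()
    agg["n_correct"] = np.where(agg["azimuth_deg"] < 0, agg["n_left"], agg["n_right"])
    agg["edge_accuracy"] = agg["n_correct"] / agg["n_total"]
    agg["edge_flag"] = agg["edge_accuracy"] < threshold
    if pooled:
        agg["condition"] = "pooled"
    return agg[["participant_id", "condition", "azimuth_deg",
                "edge_accuracy", "edge_flag"]]


def apply_exclusions(trials: pd.DataFrame,
                     fit_diagnostics: pd.DataFrame | None = None,
                     config: QCConfig | None = None):
    """Apply all exclusion rules; return (retained_trials, report).

    ``fit_diagnostics`` is the output of
    :func:`gazecone.psychometric.cone_width_pipeline` (may be None when
    fits have not been run yet; the fit rule is then skipped).  The report
    has one row per participant with every triggered reason
    (semicolon-joined, from {vigilance, edge_accuracy, fit_failure});
    ``excluded`` is true iff reasons is non-empty.  Deterministic and
    independent of participant order.
    """
    config = config or QCConfig()
    vig = vigilance_check(trials, config.vigilance_fail_threshold)
    counts = aggregate_counts(trials)
    edge = edge_accuracy_check(counts, config.edge_accuracy_threshold,
                               pooled=config.edge_pooled)
    edge_flag = edge.groupby("participant_id")["edge_flag"].any()
    edge_min = edge.groupby("participant_id")["edge_accuracy"].min()

    report = vig.set_index("participant_id")
    report["min_edge_accuracy"] = edge_min
    report["edge_flag"] = edge_flag.reindex(report.index, fill_value=False)

    if fit_diagnostics is not None and not fit_diagnostics.empty:
        fit_ok = fit_diagnostics.groupby("participant_id")["fit_ok"].all()
        # fit failure only counts for participants passing the other rules
        pre_pass = ~(report["vigilance_flag"] | report["edge_flag"])
        report["fit_ok"] = fit_ok.reindex(report.index)
        report["fit_flag"] = pre_pass & (report["fit_ok"] == False)  # noqa: E712
    else:
        report["fit_ok"] = np.nan
        report["fit_flag"] = False

    def reasons(row) -> str:
        r = []
        if row["vigilance_flag"]:
            r.append("vigilance")
        if row["edge_flag"]:
            r.append("edge_accuracy")
        if row["fit_flag"]:
            r.append("fit_failure")
        return ";".join(r)

    report["reasons"] = report.apply(reasons, axis=1)
    report["excluded"] = report["reasons"] != ""
    report = report.reset_index().sort_values("participant_id").reset_index(drop=True)

    keep = set(report.loc[~report["excluded"], "participant_id"])
    retained = trials[trials["participant_id"].isin(keep)].reset_index(drop=True)
    return retained, report
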