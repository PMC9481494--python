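"""Generative observer model and cohort simulation with known ground truth.

The generator mirrors the functional family the analysis fits: an observer
has a left and a right category boundary, and the probabilities of the
three responses follow two opposed logistic curves with the middle category
as the complement, mixed with a small lapse rate (uniformly random
responses).  Visual conditions widen the boundaries symmetrically —
the presence of a face widens the cone relative to an audio-only baseline,
and direct eye gaze widens it further — which is the effect the analysis is
built to detect.  Because the generating model and the fitted model share a
family (up to the lapse term, left in deliberately as mild
misspecification), parameter recovery is well-posed and every pipeline
stage can be verified against recorded ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import DESIGN_AZIMUTHS, TRIAL_COLUMNS
from .psychometric import find_crossings

__all__ = ["ObserverParams", "CohortSpec", "category_probabilities",
           "true_cone_width", "simulate_cohort", "ParameterError"]

CONTAMINANT_MODES = ("random_responder", "side_biased", "vigilance_failer")

#: Probability an attentive participant passes one vigilance trial.
HONEST_VIGILANCE_PASS = 0.98


class ParameterError(ValueError):
    """Observer parameters imply an invalid category distribution."""


@dataclass(frozen=True)
class ObserverParams:
    """Ground-truth observer parameters.

    boundary_left, boundary_right : degrees
        Category boundaries in the audio-only reference state
        (boundary_left < 0 < boundary_right for a typical observer).
    slope : probability per degree
        Steepness of both category transitions.
    lapse_rate : probability
        Chance of a uniformly random response, in [0, 0.1].
    face_widening : degrees per boundary
        Added to each boundary magnitude whenever a face is on screen
        (eyes_closed and direct_gaze conditions); the visual-capture effect
        of a face per se.  Default 2.0°/boundary, i.e. ≈4° of cone width.
    capture_widening : degrees per boundary
        Additional widening under direct gaze.  Default 1.5°/boundary,
        i.e. ≈3° of cone width — the magnitude of the gaze effect the
        analysis is designed to detect.
    """

    boundary_left: float = -10.0
    boundary_right: float = 10.0
    slope: float = 0.25
    lapse_rate: float = 0.02
    face_widening: float = 2.0
    capture_widening: float = 1.5

    def __post_init__(self) -> None:
        if not self.boundary_left < self.boundary_right:
            raise ParameterError("boundary_left must be below boundary_right")
        if self.slope <= 0:
            raise ParameterError("slope must be positive")
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ParameterError("lapse_rate must be in [0, 0.1]")


def _condition_boundaries(params: ObserverParams, condition: str,
                          boundary_shift: float = 0.0) -> Tuple[float, float]:
    """Boundaries after condition widening and a participant-level shift.

    The shift acts on boundary *magnitudes* (a random intercept on cone
    width); widening is cumulative: baseline +0, eyes_closed
    +face_widening, direct_gaze +face_widening+capture_widening.
    """
    widen = {"baseline": 0.0,
             "eyes_closed": params.face_widening,
             "direct_gaze": params.face_widening + params.capture_widening}
    try:
        w = widen[condition]
    except KeyError:
        raise ParameterError(f"unknown condition {condition!r}") from None
    mag_l = abs(params.boundary_left) + w + boundary_shift
    mag_r = abs(params.boundary_right) + w + boundary_shift
    bl, br = -mag_l, mag_r
    if not bl < br:
        raise ParameterError("widened boundaries collapsed (shift too negative)")
    return bl, br


def _model_probs(bl: float, br: float, slope: float, x) -> np.ndarray:
    """Lapse-free (left, middle, right) probabilities, shape (..., 3)."""
    x = np.asarray(x, dtype=float)
    pL = expit(-slope * (x - bl))
    pR = expit(slope * (x - br))
    pM = 1.0 - pL - pR
    return np.stack([pL, pM, pR], axis=-1)


def category_probabilities(params: ObserverParams, condition: str, azimuth_deg,
                           boundary_shift: float = 0.0) -> np.ndarray:
    """Response probabilities (left, middle, right) at ``azimuth_deg``.

    The lapse mixes in a uniform (1/3, 1/3, 1/3) component.  Raises
    :class:`ParameterError` if the implied middle probability is negative
    anywhere on a fine grid over ±90°.
    """
    bl, br = _condition_boundaries(params, condition, boundary_shift)
    check = _model_probs(bl, br, params.slope, np.arange(-90.0, 90.01, 0.1))
    if check[..., 1].min() < 0:
        raise ParameterError(
            f"middle probability negative for boundaries ({bl:.2f}, {br:.2f}) "
            f"at slope {params.slope}")
    p = _model_probs(bl, br, params.slope, azimuth_deg)
    return (1.0 - params.lapse_rate) * p + params.lapse_rate / 3.0


def true_cone_width(params: ObserverParams, condition: str,
                    boundary_shift: float = 0.0) -> float:
    """Ground-truth cone width: crossing distance of the lapse-free curves.

    Uses the same root-finding oracle as the analysis
    (:func:`gazecone.psychometric.find_crossings`) on the generating
    logistic parameters, so recovery checks compare like with like.
    """
    bl, br = _condition_boundaries(params, condition, boundary_shift)
    cone = find_crossings((bl, params.slope, br, params.slope))
    if cone.status != "ok":
        raise ParameterError(f"true cone undefined: {cone.status}")
    return cone.width


@dataclass
class CohortSpec:
    """Design and population of a simulated cohort.

    ``n_participants`` maps ethnicity label → count (e.g.
    ``{"white": 10, "east_asian": 10}``).  ``design`` selects the
    experiment layout: ``exp1`` = direct_gaze + eyes_closed; ``exp2`` adds
    an audio-only baseline.  ``between_participant_sd`` is the SD (degrees)
    of a normal participant-level shift added to both boundary magnitudes.
    ``contaminant_mode`` may be one mode or a sequence cycled over the
    contaminant participants.
    """

    n_participants: dict = field(default_factory=lambda: {"white": 10})
    design: str = "exp1"
    trials_per_cell: int = 10
    vigilance_trials: int = 12
    between_participant_sd: float = 3.0
    contaminant_fraction: float = 0.0
    contaminant_mode: str | Sequence[str] = "random_responder"
    seed: int = 0

    def conditions(self) -> Tuple[str, ...]:
        if self.design == "exp1":
            return ("direct_gaze", "eyes_closed")
        if self.design == "exp2":
            return ("direct_gaze", "eyes_closed", "baseline")
        raise ValueError(f"unknown design {self.design!r}")

    def modes(self) -> Tuple[str, ...]:
        m = (self.contaminant_mode,) if isinstance(self.contaminant_mode, str) \
            else tuple(self.contaminant_mode)
        for mode in m:
            if mode not in CONTAMINANT_MODES:
                raise ValueError(f"unknown contaminant mode {mode!r}")
        return m


def _contaminant_response_probs(mode: str, rng: np.random.Generator) -> Optional[np.ndarray]:
    """Flat response distribution of a contaminant, or None for honest play."""
    if mode == "random_responder":
        return np.full(3, 1.0 / 3.0)
    if mode == "side_biased":
        side = rng.integers(2)  # 0 = left-biased, 1 = right-biased
        p = np.full(3, 0.05)
        p[0 if side == 0 else 2] = 0.9
        return p
    return None  # vigilance_failer responds honestly on experimental trials


def simulate_cohort(spec: CohortSpec,
                    base: ObserverParams | None = None
                    ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort and return (trials, ground_truth).

    ``trials`` follows the canonical trial schema; ``ground_truth`` has one
    row per participant × condition with the true cone width (NaN for
    contaminants, whose behavior has no underlying cone) plus contaminant
    status and the drawn boundary shift.  Deterministic given ``spec.seed``.
    """
    base = base or ObserverParams()
    rng = np.random.default_rng(spec.seed)
    conditions = spec.conditions()
    modes = spec.modes()

    ethnicities = [e for e, n in spec.n_participants.items() for _ in range(n)]
    roster = [(f"p{idx:03d}", eth) for idx, eth in enumerate(ethnicities)]
    n_total = len(roster)
    n_contam = int(round(spec.contaminant_fraction * n_total))
    contam_ids = set(rng.choice(n_total, size=n_contam, replace=False).tolist())

    # the participant shift is truncated below so that boundary magnitudes
    # stay >= 4 degrees in every condition and the true cone remains
    # well-defined (at shallow slopes a narrower cone has no positive-width
    # crossing); with the default sd of 3 this clips ~2% of draws
    min_mag = min(abs(base.boundary_left), abs(base.boundary_right))

    trial_rows = []
    truth_rows = []
    contam_counter = 0
    for idx, (pid, eth) in enumerate(roster):
        is_contam = idx in contam_ids
        mode = None
        if is_contam:
            mode = modes[contam_counter % len(modes)]
            contam_counter += 1

        shift = float(rng.normal(0.0, spec.between_participant_sd))
        shift = max(shift, -(min_mag - 4.0))
        flat = _contaminant_response_probs(mode, rng) if is_contam else None

        for cond in conditions:
            truth_rows.append({
                "participant_id": pid, "ethnicity": eth, "condition": cond,
                "true_width": np.nan if (is_contam and mode != "vigilance_failer")
                else true_cone_width(base, cond, shift),
                "boundary_shift": shift,
                "is_contaminant": is_contam,
                "contaminant_mode": mode if is_contam else "",
            })
            if flat is not None:
                probs = np.repeat(flat[None, :], len(DESIGN_AZIMUTHS), axis=0)
            else:
                probs = category_probabilities(base, cond, DESIGN_AZIMUTHS, shift)
            # draw all trials of this condition at once
            for az, p in zip(DESIGN_AZIMUTHS, probs):
                counts = rng.multinomial(spec.trials_per_cell, p)
                for resp, k in zip(("left", "middle", "right"), counts):
                    trial_rows.extend(
                        (pid, eth, cond, "experimental", az, resp, None)
                        for _ in range(k))

        pass_p = 0.5 if (is_contam and mode == "vigilance_failer") \
            else HONEST_VIGILANCE_PASS
        passes = rng.random(spec.vigilance_trials) < pass_p
        half = spec.vigilance_trials // 2
        for j, ok in enumerate(passes):
            vtype = "vigilance_auditory" if j < half else "vigilance_visual"
            trial_rows.append((pid, eth, None, vtype, None, None, bool(ok)))

    trials = pd.DataFrame(trial_rows, columns=TRIAL_COLUMNS)
    truth = pd.DataFrame(truth_rows)
    return trials, truth
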