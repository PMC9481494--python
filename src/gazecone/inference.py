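"""Group-level inference on cone widths.

The response is one cone width per participant × condition.  The model is
a linear mixed model with a participant random intercept and no random
slopes, fitted by maximum likelihood (not REML, so log-likelihoods are
comparable across fixed-effect structures).  Significance of a fixed
effect is assessed by a likelihood-ratio test between nested models, and
post-hoc pairwise condition contrasts are built emmeans-style from the
fitted fixed effects, with t statistics on residual degrees of freedom
(observations − fixed parameters − participants).

The likelihood optimization itself is delegated to
:class:`statsmodels.regression.mixed_linear_model.MixedLM`; the model
specifications, LRT construction, contrast vectors, and df convention live
here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

__all__ = ["ModelSpec", "EffectEstimate", "LRTResult", "SpecificationError",
           "fit_mixed_model", "lrt_drop_effect", "pairwise_contrasts",
           "analyze_widths"]

#: Canonical condition ordering used for contrast labels.
CONDITION_ORDER = ("direct_gaze", "eyes_closed", "baseline")


class SpecificationError(ValueError):
    """Model specification is singular or a model pair is not nested."""


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure of the cone-width mixed model.

    The random part is always a participant intercept (no random slopes).
    """

    condition: bool = True
    ethnicity: bool = False
    interaction: bool = False

    def terms(self) -> frozenset:
        t = set()
        if self.condition:
            t.add("condition")
        if self.ethnicity:
            t.add("ethnicity")
        if self.interaction:
            if not (self.condition and self.ethnicity):
                raise SpecificationError("interaction requires both main effects")
            t.add("condition:ethnicity")
        return frozenset(t)

    def formula(self) -> str:
        parts = []
        if self.condition:
            parts.append("C(condition)")
        if self.ethnicity:
            parts.append("C(ethnicity)")
        if self.interaction:
            parts.append("C(condition):C(ethnicity)")
        rhs = " + ".join(parts) if parts else "1"
        return f"width ~ {rhs}"


@dataclass
class LRTResult:
    dropped: str
    chi2: float
    df: int
    p_value: float


@dataclass
class EffectEstimate:
    """A condition contrast (degrees) with Wald CI and t test."""

    label: str
    estimate: float
    ci_low: float
    ci_high: float
    contrast_t: float
    contrast_df: int
    p_value: float


def _check_widths(widths: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    w = widths.dropna(subset=["width"]).copy()
    n_cond = w["condition"].nunique()
    if spec.condition and n_cond < 2:
        raise SpecificationError("condition effect requested with < 2 condition levels")
    multi = w.groupby("participant_id")["condition"].nunique()
    if (multi >= 2).sum() < 2:
        raise SpecificationError("need >= 2 participants observed in >= 2 conditions")
    if spec.ethnicity and w["ethnicity"].nunique() < 2:
        raise SpecificationError("ethnicity effect requested with < 2 levels")
    return w


def fit_mixed_model(widths: pd.DataFrame, spec: ModelSpec | None = None):
    """ML fit of the random-intercept mixed model for cone widths.

    ``widths`` needs columns participant_id, condition, width (and
    ethnicity when the spec uses it).  Returns the statsmodels results
    object (coefficients ``fe_params``, random-intercept variance
    ``cov_re``, residual variance ``scale``, log-likelihood ``llf``).
    """
    spec = spec or ModelSpec()
    w = _check_widths(widths, spec)
    model = smf.mixedlm(spec.formula(), w, groups=w["participant_id"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=False)
    return res


def lrt_drop_effect(widths: pd.DataFrame, full: ModelSpec, reduced: ModelSpec,
                    label: str = "") -> LRTResult:
    """Likelihood-ratio test of ``full`` against a nested ``reduced`` model.

    chi2 = 2·(logLik_full − logLik_reduced), truncated at zero; df is the
    difference in fixed-effect parameter count; p from the chi-square
    reference distribution (p = 1 at df = 0).
    """
    if not reduced.terms() <= full.terms():
        raise SpecificationError(
            f"reduced terms {set(reduced.terms())} not nested in {set(full.terms())}")
    rf = fit_mixed_model(widths, full)
    rr = fit_mixed_model(widths, reduced)
    chi2 = max(0.0, 2.0 * (rf.llf - rr.llf))
    df = len(rf.fe_params) - len(rr.fe_params)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return LRTResult(dropped=label or str(set(full.terms()) - set(reduced.terms())),
                     chi2=float(chi2), df=int(df), p_value=p)


def _residual_df(result) -> int:
    return int(result.nobs - len(result.fe_params) - result.model.n_groups)


def _fe_cov(result) -> np.ndarray:
    names = list(result.fe_params.index)
    return result.cov_params().loc[names, names].to_numpy()


def _marginal_rows(result, data: pd.DataFrame) -> dict:
    """emmeans-style design rows: per condition level, the fixed-effect
    design vector averaged over an equally-weighted grid of the other
    factors present in the model."""
    di = result.model.data.design_info
    factors = [f for f in ("ethnicity",) if f"C({f})" in di.describe()]
    conditions = [c for c in CONDITION_ORDER if c in set(data["condition"])]
    from patsy import build_design_matrices

    rows = {}
    for cond in conditions:
        if factors:
            grid = pd.DataFrame([
                {"condition": cond, **dict(zip(factors, combo))}
                for combo in _level_product(data, factors)])
        else:
            grid = pd.DataFrame([{"condition": cond}])
        X = np.asarray(build_design_matrices([di], grid)[0])
        rows[cond] = X.mean(axis=0)
    return rows


def _level_product(data: pd.DataFrame, factors: Sequence[str]):
    from itertools import product
    levels = [sorted(data[f].dropna().unique()) for f in factors]
    return product(*levels)


def pairwise_contrasts(result, widths: pd.DataFrame,
                       within: Optional[str] = None) -> list[EffectEstimate]:
    """All pairwise condition contrasts of estimated marginal means.

    Standard errors come from the fixed-effect covariance of the fitted
    model; t statistics use residual degrees of freedom (observations −
    fixed parameters − participants); p-values are unadjusted; CIs are
    Wald intervals at the t quantile.  With ``within`` set to an ethnicity
    level, contrasts are computed at that level instead of averaging over
    ethnicity.
    """
    beta = result.fe_params.to_numpy()
    cov = _fe_cov(result)
    df = _residual_df(result)
    data = widths.dropna(subset=["width"])
    if within is not None:
        data = data.assign(ethnicity=within)
        rows = _marginal_rows(result, data)
    else:
        rows = _marginal_rows(result, data)
    conds = list(rows)
    out = []
    for i in range(len(conds)):
        for j in range(i + 1, len(conds)):
            c = rows[conds[i]] - rows[conds[j]]
            est = float(c @ beta)
            se = float(np.sqrt(c @ cov @ c))
            t = est / se if se > 0 else np.inf * np.sign(est) if est else 0.0
            tq = stats.t.ppf(0.975, df)
            p = float(2 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
            label = f"{conds[i]} - {conds[j]}" + (f" | {within}" if within else "")
            out.append(EffectEstimate(
                label=label, estimate=est, ci_low=est - tq * se,
                ci_high=est + tq * se, contrast_t=float(t), contrast_df=df,
                p_value=p))
    return out


def analyze_widths(widths: pd.DataFrame, design: str = "exp1",
                   use_ethnicity: Optional[bool] = None) -> dict:
    """Full inference report for a cone-width table.

    exp1-style: condition × ethnicity fixed effects with interaction,
    LRTs dropping each effect, marginal gaze contrast, and within-ethnicity
    post-hoc contrasts.  exp2-style (or no ethnicity): condition only, one
    LRT dropping condition, and all pairwise contrasts.

    Returns a JSON-serializable dict.
    """
    if use_ethnicity is None:
        use_ethnicity = (design == "exp1"
                         and "ethnicity" in widths.columns
                         and widths["ethnicity"].nunique() >= 2)

    report: dict = {"design": design, "n_participants":
                    int(widths.dropna(subset=["width"])["participant_id"].nunique()),
                    "lrt": [], "contrasts": []}

    if use_ethnicity:
        full = ModelSpec(condition=True, ethnicity=True, interaction=True)
        main = ModelSpec(condition=True, ethnicity=True)
        no_cond = ModelSpec(condition=False, ethnicity=True)
        no_eth = ModelSpec(condition=True, ethnicity=False)
        tests = [
            lrt_drop_effect(widths, full, main, "condition:ethnicity"),
            lrt_drop_effect(widths, main, no_cond, "condition"),
            lrt_drop_effect(widths, main, no_eth, "ethnicity"),
        ]
        fitted = fit_mixed_model(widths, full)
        contrasts = pairwise_contrasts(fitted, widths)
        for eth in sorted(widths["ethnicity"].dropna().unique()):
            contrasts.extend(pairwise_contrasts(fitted, widths, within=eth))
    else:
        full = ModelSpec(condition=True)
        null = ModelSpec(condition=False)
        tests = [lrt_drop_effect(widths, full, null, "condition")]
        fitted = fit_mixed_model(widths, full)
        contrasts = pairwise_contrasts(fitted, widths)

    report["log_likelihood"] = float(fitted.llf)
    report["random_intercept_var"] = float(np.asarray(fitted.cov_re).ravel()[0])
    report["residual_var"] = float(fitted.scale)
    report["fixed_effects"] = {k: float(v) for k, v in fitted.fe_params.items()}
    report["lrt"] = [vars(t) for t in tests]
    report["contrasts"] = [vars(c) for c in contrasts]
    return report


def summarize(report: dict) -> str:
    """Human-readable text summary of an :func:`analyze_widths` report."""
    lines = [f"Design: {report['design']}  "
             f"(n = {report['n_participants']} participants)"]
    for t in report["lrt"]:
        lines.append(
            f"LRT drop {t['dropped']}: chi2({t['df']}) = {t['chi2']:.2f}, "
            f"p = {t['p_value']:.4g}")
    for c in report["contrasts"]:
        lines.append(
            f"{c['label']}: {c['estimate']:+.2f} deg "
            f"[{c['ci_low']:.2f}, {c['ci_high']:.2f}], "
            f"t({c['contrast_df']}) = {c['contrast_t']:.2f}, "
            f"p = {c['p_value']:.4g}")
    return "\n".join(lines)
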