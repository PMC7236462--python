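"""Annual change and longitudinal tracking via multilevel linear models.

Observations in a pooled multi-study cohort are clustered as repeated
observations within child, children within study, studies within country.
Both analyses therefore use linear mixed models with random intercepts for
country, study and child (4 levels counting the residual), fitted by REML,
with Wald (normal-approximation) confidence intervals and p-values.

*Annual change* regresses a wave-level metric on time since baseline
(years), adjusted for wear time; the slope is the annual change in min/day.

*Tracking* regresses follow-up levels on baseline levels: baseline rows are
the predictor only and every eligible follow-up wave contributes one outcome
row. Predictor and outcome are z-scored (predictor by the baseline sample
mean/SD, outcome by the pooled follow-up sample mean/SD) so the coefficient
of the baseline term is a standardized tracking coefficient, classified as
low (|B| < 0.3), moderate (0.3 <= |B| <= 0.6) or high (|B| > 0.6), with "no
evidence of tracking" when p >= 0.05.

Moderation by gender or age group is tested by adding a baseline x moderator
interaction; when the interaction has p < 0.05 the analysis is stratified,
dropping the moderator from its own stratified covariate set.

Random levels that are unidentifiable in a given dataset (fewer than two
units, no grouping beyond the parent level, or one row per unit, which
confounds the child intercept with the residual) are collapsed with a
warning; with every level collapsed the fit reduces to ordinary least
squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

TRACKING_THRESHOLDS = (0.3, 0.6)
ALPHA = 0.05
DEFAULT_COVARIATES = ("wear_time", "wear_baseline", "age_baseline", "gender", "followup_duration")
RANDOM_LEVELS = ("country_id", "study_id", "participant_id")
METRICS = ("mean_total_sed", "mean_prolonged_sed", "dtd_total", "dtd_prolonged")


class ConvergenceError(RuntimeError):
    """Mixed-model optimizer failed to converge; message carries the fit log."""


@dataclass
class FitSummary:
    """Internal: one fitted fixed effect with normal-approximation inference."""

    estimate: float
    se: float
    random_levels: tuple[str, ...]
    variance_components: dict[str, float]
    n_observations: int

    @property
    def ci95(self) -> tuple[float, float]:
        half = stats.norm.ppf(0.975) * self.se
        return (self.estimate - half, self.estimate + half)

    @property
    def p_value(self) -> float:
        if self.se == 0:
            return 0.0 if self.estimate != 0 else 1.0
        z = self.estimate / self.se
        return float(2 * stats.norm.sf(abs(z)))


@dataclass
class TrackingResult:
    coefficient_std: float
    ci95: tuple[float, float]
    p_value: float
    label: str
    n_participants: int
    n_observations: int
    variance_components: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "coefficient_std": self.coefficient_std,
            "ci95": list(self.ci95),
            "p_value": self.p_value,
            "label": self.label,
            "n_participants": self.n_participants,
            "n_observations": self.n_observations,
            "variance_components": self.variance_components,
        }


@dataclass
class AnnualChangeResult:
    slope: float
    ci95: tuple[float, float]
    p_value: float
    n_participants: int
    n_observations: int
    variance_components: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "ci95": list(self.ci95),
            "p_value": self.p_value,
            "n_participants": self.n_participants,
            "n_observations": self.n_observations,
            "variance_components": self.variance_components,
        }


@dataclass
class ModeratedResult:
    moderator: str
    interaction_estimate: float
    interaction_p: float
    stratified: dict[str, TrackingResult] | None = None

    def to_dict(self) -> dict:
        return {
            "moderator": self.moderator,
            "interaction_estimate": self.interaction_estimate,
            "interaction_p": self.interaction_p,
            "stratified": (
                None
                if self.stratified is None
                else {k: v.to_dict() for k, v in self.stratified.items()}
            ),
        }


def assign_age_group(age_baseline: float, age_followup: float) -> str:
    """Age-group category from baseline and follow-up age.

    ``childhood``: both ages <= 12; ``transition``: baseline <= 12 and
    follow-up > 12; ``adolescence``: both > 12 (rare in practice and
    typically excluded from stratified analyses).
    """
    if age_followup <= age_baseline:
        raise ValueError(
            f"follow-up age ({age_followup}) must exceed baseline age ({age_baseline})"
        )
    if age_baseline <= 12 and age_followup <= 12:
        return "childhood"
    if age_baseline <= 12:
        return "transition"
    return "adolescence"


def classify_tracking(
    coefficient_std: float,
    p_value: float,
    thresholds: tuple[float, float] = TRACKING_THRESHOLDS,
    alpha: float = ALPHA,
) -> str:
    """Map a standardized tracking coefficient and p-value to a label.

    ``none`` when p >= alpha (no evidence of tracking); otherwise by |B|:
    low below the first threshold, high above the second, moderate in the
    closed interval between them.
    """
    if p_value >= alpha:
        return "none"
    b = abs(coefficient_std)
    low, high = thresholds
    if b < low:
        return "low"
    if b > high:
        return "high"
    return "moderate"


def build_cohort_table(summary: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Reshape wave summaries into the tracking-analysis table for one metric.

    One output row per (participant, follow-up wave) for participants with a
    baseline (wave 1) summary; baseline values are carried as predictors and
    never appear as outcome rows.
    """
    if metric not in summary.columns:
        raise KeyError(f"metric column {metric!r} absent from wave summaries")
    base = summary[summary["wave"] == 1].set_index("participant_id")
    follow = summary[summary["wave"] >= 2]
    follow = follow[follow["participant_id"].isin(base.index)]
    rows = pd.DataFrame(
        {
            "participant_id": follow["participant_id"].to_numpy(),
            "study_id": follow["study_id"].to_numpy(),
            "country_id": follow["country_id"].to_numpy(),
            "wave": follow["wave"].to_numpy(),
            "outcome_value": follow[metric].to_numpy(dtype=float),
            "baseline_value": base.loc[follow["participant_id"], metric].to_numpy(dtype=float),
            "age_baseline": base.loc[follow["participant_id"], "age"].to_numpy(dtype=float),
            "age_followup": follow["age"].to_numpy(dtype=float),
            "gender": follow["gender"].to_numpy(),
            "wear_time": follow["mean_wear"].to_numpy(dtype=float),
            "wear_baseline": base.loc[follow["participant_id"], "mean_wear"].to_numpy(dtype=float),
        }
    )
    rows["time_since_baseline"] = rows["age_followup"] - rows["age_baseline"]
    rows["followup_duration"] = rows["time_since_baseline"]
    if (rows["time_since_baseline"] <= 0).any():
        bad = rows.loc[rows["time_since_baseline"] <= 0, "participant_id"].unique()
        raise ValueError(f"non-positive follow-up time for participants {bad.tolist()}")
    return rows.reset_index(drop=True)


def build_long_table(summary: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Long table (all waves, baseline included) for annual-change models."""
    if metric not in summary.columns:
        raise KeyError(f"metric column {metric!r} absent from wave summaries")
    base_age = (
        summary[summary["wave"] == 1].set_index("participant_id")["age"]
    )
    df = summary[summary["participant_id"].isin(base_age.index)].copy()
    df["outcome_value"] = df[metric].astype(float)
    df["time_since_baseline"] = (
        df["age"].to_numpy(dtype=float)
        - base_age.loc[df["participant_id"]].to_numpy(dtype=float)
    )
    df["wear_time"] = df["mean_wear"].astype(float)
    return df.reset_index(drop=True)


def _identifiable_levels(
    data: pd.DataFrame, levels: Sequence[str] = RANDOM_LEVELS
) -> list[str]:
    """Random levels that are identifiable in this dataset (see module docs)."""
    kept: list[str] = []
    n = len(data)
    prev_groups = 1
    for lvl in levels:
        k = data[lvl].nunique()
        if k < 2 or k <= prev_groups or k >= n:
            warnings.warn(
                f"random level {lvl!r} collapsed ({k} units over {n} rows)",
                stacklevel=3,
            )
            continue
        kept.append(lvl)
        prev_groups = k
    return kept


def _drop_degenerate_terms(data: pd.DataFrame, covariates: Sequence[str]) -> list[str]:
    terms = []
    for cov in covariates:
        if cov not in data.columns:
            raise KeyError(f"covariate column {cov!r} missing")
        if data[cov].nunique() < 2:
            continue  # constant column carries no information
        terms.append(f"C({cov})" if data[cov].dtype == object else cov)
    return terms


def _fit_mixed(data: pd.DataFrame, formula: str):
    """Fit the nested random-intercept model, collapsing to OLS when no random
    level is identifiable. Returns (results, kept_levels, variance_components).

    Powell is tried first: near-boundary variance estimates (common with few
    countries/studies) trip the gradient optimizers' convergence flags even
    when the solution is fine.
    """
    levels = _identifiable_levels(data)
    log: list[str] = []
    while levels:
        vc = {lvl: f"0 + C({lvl})" for lvl in levels[1:]}
        model = smf.mixedlm(
            formula,
            data=data,
            groups=data[levels[0]],
            re_formula="1",
            vc_formula=vc or None,
        )
        res = None
        for method in ("powell", "lbfgs", "cg"):
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                try:
                    candidate = model.fit(reml=True, method=method)
                except Exception as exc:  # singular matrices etc.
                    log.append(f"{method}: {exc}")
                    continue
            log.extend(f"{method}: {w.message}" for w in caught)
            if candidate.converged:
                res = candidate
                break
            log.append(f"{method}: optimizer did not converge")
        if res is not None:
            vcomp = {levels[0]: float(res.cov_re.iloc[0, 0])}
            for name, value in zip(vc.keys(), np.atleast_1d(res.vcomp)):
                vcomp[name] = float(value)
            vcomp["residual"] = float(res.scale)
            return res, tuple(levels), vcomp
        # singular fit: collapse the finest remaining level and retry
        dropped = levels.pop()
        warnings.warn(
            f"random level {dropped!r} collapsed after singular/non-converged fit"
        )
    if log:
        warnings.warn(
            "all random levels collapsed; fitting by OLS. Fit log:\n" + "\n".join(log)
        )
    res = smf.ols(formula, data=data).fit()
    return res, (), {"residual": float(res.mse_resid)}


def _fit_lmm(data: pd.DataFrame, formula: str, term: str) -> FitSummary:
    """Inference for one fixed-effect ``term`` from the nested model."""
    res, levels, vcomp = _fit_mixed(data, formula)
    return FitSummary(
        estimate=float(res.params[term]),
        se=float(res.bse[term]),
        random_levels=levels,
        variance_components=vcomp,
        n_observations=int(res.nobs),
    )


def _standardize(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add z-scored predictor and outcome columns.

    The predictor is z-scored against the baseline sample (one value per
    participant); the outcome against the pooled follow-up sample.
    """
    data = cohort.copy()
    base = data.drop_duplicates("participant_id")["baseline_value"]
    sd_b = float(base.std(ddof=1))
    sd_o = float(data["outcome_value"].std(ddof=1))
    if not (sd_b > 0) or not (sd_o > 0):
        raise ValueError("cannot standardize: zero variance in baseline or outcome")
    data["z_base"] = (data["baseline_value"] - float(base.mean())) / sd_b
    data["z_out"] = (data["outcome_value"] - float(data["outcome_value"].mean())) / sd_o
    return data


def fit_tracking(
    cohort: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> TrackingResult:
    """Standardized longitudinal tracking coefficient for one metric.

    ``cohort`` is a table from :func:`build_cohort_table`. Returns the
    coefficient of the z-scored baseline value from the multilevel model,
    with Wald 95% CI, p-value and the tracking label.
    """
    n_participants = cohort["participant_id"].nunique()
    if n_participants < 2:
        raise ValueError("tracking requires at least 2 distinct participants")
    data = _standardize(cohort)
    terms = _drop_degenerate_terms(data, covariates)
    formula = " + ".join(["z_out ~ z_base"] + terms)
    fit = _fit_lmm(data, formula, "z_base")
    return TrackingResult(
        coefficient_std=fit.estimate,
        ci95=fit.ci95,
        p_value=fit.p_value,
        label=classify_tracking(fit.estimate, fit.p_value),
        n_participants=int(n_participants),
        n_observations=fit.n_observations,
        variance_components=fit.variance_components,
    )


def fit_annual_change(
    long_table: pd.DataFrame,
    covariates: Sequence[str] = ("wear_time",),
) -> AnnualChangeResult:
    """Annual change (min/day per year) of a metric from the long table."""
    if long_table["participant_id"].nunique() < 2:
        raise ValueError("annual change requires at least 2 distinct participants")
    terms = _drop_degenerate_terms(long_table, covariates)
    formula = " + ".join(["outcome_value ~ time_since_baseline"] + terms)
    fit = _fit_lmm(long_table, formula, "time_since_baseline")
    return AnnualChangeResult(
        slope=fit.estimate,
        ci95=fit.ci95,
        p_value=fit.p_value,
        n_participants=int(long_table["participant_id"].nunique()),
        n_observations=fit.n_observations,
        variance_components=fit.variance_components,
    )


def add_age_group(cohort: pd.DataFrame) -> pd.DataFrame:
    """Attach a per-participant age-group column to a cohort table.

    With more than one follow-up wave the group is assigned from baseline age
    and the age at the participant's last eligible follow-up.
    """
    last = cohort.sort_values("wave").groupby("participant_id").tail(1)
    groups = {
        row.participant_id: assign_age_group(row.age_baseline, row.age_followup)
        for row in last.itertuples()
    }
    out = cohort.copy()
    out["age_group"] = out["participant_id"].map(groups)
    return out


_STRATIFIED_COVARIATES = {
    # moderator dropped from its own stratified adjustment set
    "gender": ("wear_time", "wear_baseline", "age_baseline", "followup_duration"),
    "age_group": ("wear_time", "wear_baseline", "gender", "followup_duration"),
}


def test_moderation(
    cohort: pd.DataFrame,
    moderator: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    alpha: float = ALPHA,
) -> ModeratedResult:
    """Test moderation of tracking by ``gender`` or ``age_group``.

    Adds a baseline x moderator interaction to the tracking model; when the
    interaction is significant at ``alpha``, refits stratified models per
    moderator level. Participants in the rare ``adolescence`` age group are
    excluded from age-group moderation.
    """
    if moderator == "age_group" and "age_group" not in cohort.columns:
        cohort = add_age_group(cohort)
    if moderator not in cohort.columns:
        raise KeyError(f"moderator column {moderator!r} missing")
    data = cohort[cohort[moderator] != "adolescence"] if moderator == "age_group" else cohort
    level_sizes = data.groupby(moderator)["participant_id"].nunique()
    if (level_sizes >= 2).sum() < 2:
        raise ValueError(
            f"moderator {moderator!r} needs >=2 levels with >=2 participants; "
            f"got {level_sizes.to_dict()}"
        )
    data = _standardize(data)
    terms = _drop_degenerate_terms(data, [c for c in covariates if c != moderator])
    formula = " + ".join([f"z_out ~ z_base * C({moderator})"] + terms)
    # interaction inference needs the full parameter vector, not one term
    res, _, _ = _fit_mixed(data, formula)
    inter = [p for p in res.params.index if p.startswith("z_base:")]
    if not inter:
        raise ValueError(f"interaction with {moderator!r} inestimable")
    if len(inter) == 1:
        est = float(res.params[inter[0]])
        se = float(res.bse[inter[0]])
        p = float(2 * stats.norm.sf(abs(est / se))) if se > 0 else 1.0
    else:  # joint Wald chi-square across interaction terms
        b = res.params[inter].to_numpy()
        cov = res.cov_params().loc[inter, inter].to_numpy()
        w = float(b @ np.linalg.solve(cov, b))
        p = float(stats.chi2.sf(w, df=len(inter)))
        est = float(np.max(np.abs(b)))
    stratified = None
    if p < alpha:
        stratified = {}
        strat_cov = _STRATIFIED_COVARIATES.get(
            moderator, tuple(c for c in covariates if c != moderator)
        )
        for level, grp in data.groupby(moderator):
            if grp["participant_id"].nunique() < 2:
                warnings.warn(f"stratum {level!r} skipped (too few participants)")
                continue
            stratified[str(level)] = fit_tracking(grp, covariates=strat_cov)
    return ModeratedResult(
        moderator=moderator,
        interaction_estimate=est,
        interaction_p=p,
        stratified=stratified,
    )
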