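"""Mixed-model analysis of biomarker-SNI associations in a repeated-visits cohort.

All inference runs through linear mixed-effects models (LMEM) with a random
intercept per subject, which accounts for the repeated annual visits.  Three
workflows are provided:

* :func:`screen_biomarkers` — one joint LMEM with SNI as dependent variable
  and age plus the seven serum biomarkers as covariates, reporting each
  covariate's slope, p-value and sign.
* :func:`test_moderation` — does a binary factor (genotype carriage or virus
  serostatus) change the pTau217→SNI slope?  A factor x biomarker
  interaction term tests slope parallelism; if it rejects, the two stratified
  slopes are compared directly with the slope-difference normal deviate
  Z = (b1 - b2) / sqrt(SE1^2 + SE2^2) (Paternoster test).
* :func:`moca_models` — MoCA as dependent variable: age (plus each biomarker
  in turn), the pTau217 x SNI interaction, and the same interaction model
  stratified by HLA-DRB1*13 carriage.

P-values are two-sided Wald tests; no multiplicity correction is applied by
default (an optional Holm adjustment is available on the screen).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import BIOMARKERS, VIRUSES

__all__ = [
    "FitResult",
    "ModerationResult",
    "fit_lmem",
    "paternoster_z",
    "screen_biomarkers",
    "test_moderation",
    "moca_models",
    "MocaResults",
    "prepare_apoe_factor",
]

ALPHA_DEFAULT = 0.05


@dataclass
class FitResult:
    """Term table of one mixed-model fit."""

    terms: pd.DataFrame  # columns: term, estimate, se, p
    n_obs: int
    n_subjects: int
    converged: bool
    formula: str

    def term(self, name: str) -> pd.Series:
        hit = self.terms[self.terms["term"] == name]
        if hit.empty:
            raise KeyError(f"term {name!r} not in fit ({list(self.terms['term'])})")
        return hit.iloc[0]

    def slope(self, name: str) -> tuple[float, float]:
        """(estimate, SE) for a named term."""
        row = self.term(name)
        return float(row["estimate"]), float(row["se"])

    def p(self, name: str) -> float:
        return float(self.term(name)["p"])

    def ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        """Confidence interval for a term.

        Uses a t quantile with subjects-minus-parameters degrees of freedom
        rather than the normal quantile: with few clusters (e.g. a small
        carrier stratum) the Wald normal interval undercovers, and the
        cluster-count df is the usual conservative correction.
        """
        b, se = self.slope(name)
        df = max(self.n_subjects - len(self.terms), 1)
        half = stats.t.ppf(0.5 + level / 2.0, df) * se
        return (b - half, b + half)


def _check_factor(df: pd.DataFrame, col: str) -> None:
    levels = df[col].dropna().unique()
    if len(levels) < 2:
        raise ValueError(
            f"factor {col!r} has a single observed level ({levels.tolist()}); "
            "no contrast exists, so the model cannot be fit"
        )


def fit_lmem(
    table: pd.DataFrame,
    dependent: str,
    covariates: Sequence[str] = (),
    factors: Sequence[str] = (),
    interactions: Sequence[tuple[str, str]] = (),
    groups: str = "subject_id",
    reml: bool = True,
) -> FitResult:
    """Fit a random-intercept LMEM and return its fixed-effect term table.

    Rows with a missing value in any model variable are dropped (listwise
    deletion); ``n_obs`` reports the rows actually used.  Factors must have
    both levels observed after deletion.  Estimation delegates to
    statsmodels' MixedLM; non-convergence is flagged on the result rather
    than raised.
    """
    cols = [dependent, *covariates, *factors, groups]
    for a, b in interactions:
        cols += [a, b]
    cols = list(dict.fromkeys(cols))
    missing_cols = [c for c in cols if c not in table.columns]
    if missing_cols:
        raise KeyError(f"columns not in table: {missing_cols}")
    df = table[cols].dropna().copy()
    for f in factors:
        _check_factor(df, f)
    if df[groups].nunique() < 2:
        raise ValueError("need at least 2 subjects to fit a mixed model")

    # binary 0/1 factors enter numerically; string factors get dummy coding
    df[dependent] = df[dependent].astype(float)
    rhs_terms: list[str] = []
    for c in covariates:
        df[c] = df[c].astype(float)
        rhs_terms.append(c)
    for f in factors:
        if not pd.api.types.is_numeric_dtype(df[f]):
            df[f] = pd.Categorical(df[f]).codes
        df[f] = df[f].astype(float)
        rhs_terms.append(f)
    for a, b in interactions:
        for c in (a, b):
            if not pd.api.types.is_numeric_dtype(df[c]):
                df[c] = pd.Categorical(df[c]).codes
            df[c] = df[c].astype(float)
        rhs_terms.append(f"{a}:{b}")

    formula = f"{dependent} ~ " + " + ".join(rhs_terms) if rhs_terms else f"{dependent} ~ 1"
    import statsmodels.formula.api as smf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df[groups])
        try:
            res = model.fit(reml=reml)
            converged = bool(getattr(res, "converged", True))
        except Exception:
            res = model.fit(reml=reml, method="powell")
            converged = bool(getattr(res, "converged", False))

    fe = res.fe_params
    terms = pd.DataFrame(
        {
            "term": list(fe.index),
            "estimate": [float(fe[t]) for t in fe.index],
            "se": [float(res.bse[t]) for t in fe.index],
            "p": [float(res.pvalues[t]) for t in fe.index],
        }
    )
    return FitResult(
        terms=terms,
        n_obs=int(len(df)),
        n_subjects=int(df[groups].nunique()),
        converged=converged,
        formula=formula,
    )


def paternoster_z(b1: float, se1: float, b2: float, se2: float) -> tuple[float, float]:
    """Slope-difference normal deviate and its two-sided p-value.

    Z = (b1 - b2) / sqrt(SE1^2 + SE2^2); antisymmetric under swapping the
    two slopes.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    z = (b1 - b2) / np.hypot(se1, se2)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def screen_biomarkers(
    table: pd.DataFrame,
    alpha: float = ALPHA_DEFAULT,
    joint: bool = True,
    holm: bool = False,
) -> pd.DataFrame:
    """Screen age and the seven biomarkers for association with SNI.

    By default one joint LMEM with all eight covariates; ``joint=False``
    instead fits seven separate age-controlled models (one per biomarker).
    Returns one row per predictor with estimate, SE, p and a direction label
    ('positive'/'negative' when p < alpha, else 'NS').  Biomarker columns
    that are entirely missing are skipped with a warning.
    """
    usable = []
    for b in BIOMARKERS:
        if b not in table.columns or table[b].dropna().empty:
            warnings.warn(f"biomarker column {b!r} absent or all-missing; skipped")
            continue
        usable.append(b)
    predictors = ["age"] + usable

    rows = []
    if joint:
        fit = fit_lmem(table, "sni", covariates=predictors)
        for name in predictors:
            est, se = fit.slope(name)
            rows.append({"predictor": name, "estimate": est, "se": se, "p": fit.p(name), "n_obs": fit.n_obs})
    else:
        age_fit = fit_lmem(table, "sni", covariates=["age"])
        est, se = age_fit.slope("age")
        rows.append({"predictor": "age", "estimate": est, "se": se, "p": age_fit.p("age"), "n_obs": age_fit.n_obs})
        for b in usable:
            fit = fit_lmem(table, "sni", covariates=["age", b])
            est, se = fit.slope(b)
            rows.append({"predictor": b, "estimate": est, "se": se, "p": fit.p(b), "n_obs": fit.n_obs})

    out = pd.DataFrame(rows)
    pvals = out["p"].to_numpy()
    if holm:
        from statsmodels.stats.multitest import multipletests

        pvals = multipletests(pvals, method="holm")[1]
        out["p_adjusted"] = pvals
    out["association"] = [
        ("positive" if e > 0 else "negative") if p < alpha else "NS"
        for e, p in zip(out["estimate"], pvals)
    ]
    return out


@dataclass
class ModerationResult:
    """Outcome of a factor x biomarker slope-moderation analysis.

    ``slope_absent``/``slope_present`` are (estimate, SE) pairs from the two
    stratified fits; they and the Paternoster fields are None when the
    interaction term did not reach ``alpha`` (and stratification was not
    forced).  ``direction`` states which group has the larger slope.
    """

    factor: str
    biomarker: str
    interaction_estimate: float
    interaction_p: float
    alpha: float
    n_obs: int
    n_absent: int = 0
    n_present: int = 0
    slope_absent: tuple[float, float] | None = None
    slope_present: tuple[float, float] | None = None
    paternoster_z: float | None = None
    paternoster_p: float | None = None
    direction: str | None = None
    joint_fit: FitResult | None = field(default=None, repr=False)
    stratified_fits: dict | None = field(default=None, repr=False)

    @property
    def significant(self) -> bool:
        return self.interaction_p < self.alpha

    def summary(self) -> dict:
        return {
            "factor": self.factor,
            "biomarker": self.biomarker,
            "interaction_p": self.interaction_p,
            "slope_absent": self.slope_absent,
            "slope_present": self.slope_present,
            "paternoster_z": self.paternoster_z,
            "paternoster_p": self.paternoster_p,
            "direction": self.direction,
        }


def test_moderation(
    table: pd.DataFrame,
    factor: str,
    biomarker: str = "ptau217",
    covariates: Sequence[str] = ("age",),
    alpha: float = ALPHA_DEFAULT,
    always_stratify: bool = False,
    min_stratum_subjects: int = 3,
) -> ModerationResult:
    """Test whether a binary factor moderates the biomarker→SNI slope.

    Step 1 fits the joint LMEM ``sni ~ covariates + biomarker + factor +
    factor:biomarker``.  Step 2 — only when the interaction p-value falls
    below ``alpha`` (or ``always_stratify``) — fits ``sni ~ covariates +
    biomarker`` separately in the factor-absent and factor-present strata.
    Step 3 compares the two stratified slopes with the Paternoster Z.

    The factor column must be binary 0/1 (absent/present) with both levels
    observed; a constant column (e.g. a virus with 100% seroprevalence)
    raises, since no moderation contrast exists.
    """
    _check_factor(table.dropna(subset=[factor, biomarker, "sni"]), factor)
    levels = sorted(pd.unique(table[factor].dropna()))
    if len(levels) != 2:
        raise ValueError(f"factor {factor!r} must be binary, found levels {levels}")

    joint = fit_lmem(
        table,
        "sni",
        covariates=[*covariates, biomarker],
        factors=[factor],
        interactions=[(factor, biomarker)],
    )
    inter_name = f"{factor}:{biomarker}"
    inter_est, _ = joint.slope(inter_name)
    inter_p = joint.p(inter_name)

    result = ModerationResult(
        factor=factor,
        biomarker=biomarker,
        interaction_estimate=inter_est,
        interaction_p=inter_p,
        alpha=alpha,
        n_obs=joint.n_obs,
        joint_fit=joint,
    )
    if not (inter_p < alpha or always_stratify):
        return result

    strata: dict[int, FitResult] = {}
    slopes: dict[int, tuple[float, float]] = {}
    for lev in (levels[0], levels[1]):
        sub = table[table[factor] == lev]
        n_subj = sub["subject_id"].nunique()
        if n_subj < min_stratum_subjects:
            warnings.warn(
                f"stratum {factor}={lev} has only {n_subj} subjects; stratified fit skipped"
            )
            return result
        fit = fit_lmem(sub, "sni", covariates=[*covariates, biomarker])
        strata[int(lev)] = fit
        slopes[int(lev)] = fit.slope(biomarker)

    (b_abs, se_abs), (b_pres, se_pres) = slopes[0], slopes[1]
    z, p = paternoster_z(b_abs, se_abs, b_pres, se_pres)
    result.slope_absent = (b_abs, se_abs)
    result.slope_present = (b_pres, se_pres)
    result.paternoster_z = z
    result.paternoster_p = p
    result.direction = "absent > present" if b_abs > b_pres else "present > absent"
    result.n_absent = strata[0].n_obs
    result.n_present = strata[1].n_obs
    result.stratified_fits = strata
    return result


def prepare_apoe_factor(table: pd.DataFrame) -> pd.DataFrame:
    """Restrict to the ApoE2 and ApoE4 groups and add a binary ``apoe4`` column.

    Rows whose genotype falls in neither group (e3e3, e2e4) or is missing are
    excluded — the ApoE contrast is defined only between the two groups.
    """
    sub = table[table["apoe_group"].isin(["ApoE2", "ApoE4"])].copy()
    sub["apoe4"] = (sub["apoe_group"] == "ApoE4").astype(int)
    return sub


def screen_virus_moderation(
    table: pd.DataFrame,
    biomarker: str = "ptau217",
    viruses: Sequence[str] = tuple(VIRUSES),
    alpha: float = ALPHA_DEFAULT,
) -> dict[str, ModerationResult]:
    """Run the moderation analysis for each virus serostatus column.

    Rows with missing serostatus are dropped per virus, not globally.  A
    virus whose observed serostatus is constant (no contrast) is skipped
    with a warning rather than failing the whole screen.
    """
    out: dict[str, ModerationResult] = {}
    for v in viruses:
        try:
            out[v] = test_moderation(table, v, biomarker=biomarker, alpha=alpha)
        except ValueError as exc:
            warnings.warn(f"virus {v!r} skipped: {exc}")
    return out


@dataclass
class MocaResults:
    """The three MoCA workflows: age (+each biomarker), the pTau217 x SNI
    interaction model, and that model stratified by HLA carriage."""

    age_model: FitResult
    biomarker_models: dict[str, FitResult]
    interaction_model: FitResult
    stratified: dict[tuple[str, int], FitResult]

    def interaction_p(self, factor: str | None = None, level: int | None = None) -> float:
        fit = self.interaction_model if factor is None else self.stratified[(factor, level)]
        return fit.p("ptau217:sni")


def moca_models(
    table: pd.DataFrame,
    hla_factors: Sequence[str] = ("drb1_1301", "drb1_1302"),
) -> MocaResults:
    """Fit the MoCA models.

    Model A: ``moca ~ age``, then each biomarker in turn controlling for age.
    Model B: ``moca ~ age + sni + ptau217 + ptau217:sni``.
    Model C: model B within each level of each HLA carriage factor.
    """
    age_model = fit_lmem(table, "moca", covariates=["age"])
    biomarker_models = {
        b: fit_lmem(table, "moca", covariates=["age", b])
        for b in BIOMARKERS
        if b in table.columns and not table[b].dropna().empty
    }
    interaction_model = fit_lmem(
        table,
        "moca",
        covariates=["age", "sni", "ptau217"],
        interactions=[("ptau217", "sni")],
    )
    stratified: dict[tuple[str, int], FitResult] = {}
    for f in hla_factors:
        for lev in (0, 1):
            sub = table[table[f] == lev]
            stratified[(f, lev)] = fit_lmem(
                sub,
                "moca",
                covariates=["age", "sni", "ptau217"],
                interactions=[("ptau217", "sni")],
            )
    return MocaResults(
        age_model=age_model,
        biomarker_models=biomarker_models,
        interaction_model=interaction_model,
        stratified=stratified,
    )
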