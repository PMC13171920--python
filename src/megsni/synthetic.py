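"""Synthetic cohort and MEG-like recording generators.

The generators provide ground-truth-known stand-ins for a longitudinal
brain-aging study design: ~175 women with annual visits (~348 acquisitions
total), seven serum biomarkers of dementia and neurodegeneration, ApoE and
HLA-DRB1*13 genotypes, IgG serostatus for eight virus groups, a MoCA
cognitive score, and a per-scan SNI value.  The SNI column is generated from
an explicit linear model whose pTau217 slope can differ by genotype or
serostatus group — the moderation effects the analysis pipeline is meant to
recover.

MEG-like recordings are built by a latent-factor construction (shared factor
plus independent channel noise), which makes the target zero-lag correlation
analytically exact in expectation, optionally followed by a common AR
coloring filter that adds temporal autocorrelation without changing the
zero-lag cross-channel correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .sni import MegRecording

__all__ = [
    "CohortScenario",
    "MegScenario",
    "SniModel",
    "MocaModel",
    "SimulatedCohort",
    "generate_cohort",
    "generate_meg",
    "default_cohort_scenario",
    "default_meg_scenario",
    "write_cohort",
    "read_cohort",
    "BIOMARKERS",
    "VIRUSES",
    "APOE_GENOTYPE_COUNTS",
    "HLA_CARRIER_COUNTS",
    "SERO_COUNTS",
    "BIOMARKER_MEAN_MEDIAN",
]

BIOMARKERS = ["abeta40", "abeta42", "abeta_ratio", "nfl", "ttau", "ptau181", "ptau217"]
VIRUSES = ["hhv1", "hhv2", "hhv4", "hhv5", "hhv6", "hervk", "hervw", "hpv"]

# Cohort template counts used to set the default population parameters.
# ApoE genotypes over the 174 participants with a determination; the ApoE2
# group is {e2e2, e3e2} and the ApoE4 group is {e4e4, e4e3}; e3e3 and e2e4
# belong to neither group.
APOE_GENOTYPE_COUNTS: dict[str, int] = {
    "e2e2": 1,
    "e3e2": 22,
    "e2e4": 3,
    "e3e3": 108,
    "e4e3": 34,
    "e4e4": 6,
}
# HLA-DRB1 carrier counts out of 175 typed participants.
HLA_CARRIER_COUNTS: dict[str, tuple[int, int]] = {
    "drb1_1301": (22, 175),
    "drb1_1302": (15, 175),
}
# (seropositive, unambiguous tests) per virus group across 348 acquisitions.
# The varicella-zoster group is absent: with 100% seropositivity it carries
# no contrast and is excluded from moderation analyses by design.
SERO_COUNTS: dict[str, tuple[int, int]] = {
    "hhv1": (198, 345),
    "hhv2": (77, 342),
    "hhv4": (333, 346),
    "hhv5": (185, 347),
    "hhv6": (304, 331),
    "hervk": (238, 348),
    "hervw": (317, 348),
    "hpv": (183, 348),
}
# Serum biomarker (mean, median); pg/ml except the unitless Abeta42/40 ratio.
BIOMARKER_MEAN_MEDIAN: dict[str, tuple[float, float]] = {
    "abeta40": (53.4, 46.3),
    "abeta42": (8.33, 7.78),
    "abeta_ratio": (0.208, 0.149),
    "nfl": (52.5, 32.1),
    "ttau": (3.51, 2.53),
    "ptau181": (0.441, 0.250),
    "ptau217": (1.070, 0.545),
}


def _lognormal_params(mean: float, median: float) -> tuple[float, float]:
    """Location/scale of a log-normal matching a printed mean and median.

    median = exp(mu) and mean = exp(mu + sigma^2/2), so
    sigma = sqrt(2 ln(mean/median)); requires mean >= median (right skew).
    """
    if mean < median or median <= 0:
        raise ValueError("log-normal moment matching needs mean >= median > 0")
    return math.log(median), math.sqrt(2.0 * math.log(mean / median))


@dataclass(frozen=True)
class SniModel:
    """Generative linear model for the per-scan SNI value.

    SNI = intercept + age_slope * age + (ptau217_slope + sum of active
    slope_offsets) * pTau217 + subject intercept + residual.  Offsets are
    keyed by factor column name ('drb1_1301', 'hhv1', ...; 'apoe4'/'apoe2'
    refer to the ApoE group indicator) and are active when the subject
    carries / is seropositive for that factor.
    """

    intercept: float = 0.0318
    age_slope: float = 5.0e-5
    ptau217_slope: float = 0.0015
    slope_offsets: Mapping[str, float] = field(default_factory=lambda: {"drb1_1301": -0.0025})
    subject_sd: float = 0.003
    residual_sd: float = 0.003


@dataclass(frozen=True)
class MocaModel:
    """Generative model for the MoCA score (rounded, clipped to 0-30).

    MoCA declines with age and with the pTau217 x SNI product; a protective
    factor with protection fraction q scales the product slope by (1 - q)
    when carried, so full protection (q = 1) by either HLA allele cancels
    the term outright and carrying both cannot overshoot.
    """

    intercept: float = 31.4
    age_slope: float = -0.05
    ptau_sni_slope: float = -15.0
    protection: Mapping[str, float] = field(
        default_factory=lambda: {"drb1_1301": 1.0, "drb1_1302": 1.0}
    )
    subject_sd: float = 1.0
    residual_sd: float = 1.0


def _default_biomarker_params() -> dict[str, tuple[float, float]]:
    return {k: _lognormal_params(m, md) for k, (m, md) in BIOMARKER_MEAN_MEDIAN.items()}


def _default_apoe_probs() -> dict[str, float]:
    total = sum(APOE_GENOTYPE_COUNTS.values())
    return {g: n / total for g, n in APOE_GENOTYPE_COUNTS.items()}


@dataclass(frozen=True)
class CohortScenario:
    """Population parameters for a synthetic repeated-visits cohort."""

    n_subjects: int = 175
    # P(1 visit), P(2 visits), ...; default gives ~1.99 visits/subject,
    # i.e. ~348 expected acquisitions from 175 subjects.
    visit_weights: tuple[float, ...] = (0.40, 0.31, 0.19, 0.10)
    age_mean: float = 69.2  # acquisition-level mean, years
    age_sd: float = 11.75
    biomarker_params: Mapping[str, tuple[float, float]] = field(default_factory=_default_biomarker_params)
    biomarker_log_corr: float = 0.3
    apoe_genotype_probs: Mapping[str, float] = field(default_factory=_default_apoe_probs)
    drb1_1301_freq: float = HLA_CARRIER_COUNTS["drb1_1301"][0] / HLA_CARRIER_COUNTS["drb1_1301"][1]
    drb1_1302_freq: float = HLA_CARRIER_COUNTS["drb1_1302"][0] / HLA_CARRIER_COUNTS["drb1_1302"][1]
    sero_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {v: k / n for v, (k, n) in SERO_COUNTS.items()}
    )
    sni_model: SniModel = field(default_factory=SniModel)
    moca_model: MocaModel = field(default_factory=MocaModel)
    missingness_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "abeta_ratio": 35 / 348,
            "nfl": 1 / 348,
            "ttau": 30 / 348,
            "hhv1": 3 / 348,
            "hhv2": 6 / 348,
            "hhv4": 2 / 348,
            "hhv5": 1 / 348,
            "hhv6": 17 / 348,
        }
    )
    apoe_missing_freq: float = 1 / 175  # subject-level undetermined genotype
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        w = np.asarray(self.visit_weights, dtype=float)
        if w.size == 0 or np.any(w < 0) or not math.isclose(w.sum(), 1.0, abs_tol=1e-8):
            raise ValueError("visit_weights must be non-negative and sum to 1")
        probs = [self.drb1_1301_freq, self.drb1_1302_freq, self.apoe_missing_freq]
        probs += list(self.sero_prevalence.values())
        probs += list(self.missingness_rates.values())
        probs += list(self.apoe_genotype_probs.values())
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if not math.isclose(sum(self.apoe_genotype_probs.values()), 1.0, abs_tol=1e-8):
            raise ValueError("apoe_genotype_probs must sum to 1")
        for m in (self.sni_model, self.moca_model):
            if m.subject_sd < 0 or m.residual_sd < 0:
                raise ValueError("model SDs must be non-negative")
        if any(q < 0 or q > 1 for q in self.moca_model.protection.values()):
            raise ValueError("protection fractions must lie in [0, 1]")
        if self.age_sd < 0:
            raise ValueError("age_sd must be non-negative")

    @property
    def expected_visits_per_subject(self) -> float:
        return float(sum((i + 1) * w for i, w in enumerate(self.visit_weights)))

    @property
    def expected_rows(self) -> float:
        return self.n_subjects * self.expected_visits_per_subject

    def factor_prevalence(self, name: str) -> float:
        """Population frequency of a binary factor used in slope offsets."""
        if name == "drb1_1301":
            return self.drb1_1301_freq
        if name == "drb1_1302":
            return self.drb1_1302_freq
        if name in self.sero_prevalence:
            return self.sero_prevalence[name]
        probs = self.apoe_genotype_probs
        if name == "apoe4":
            return probs.get("e4e4", 0.0) + probs.get("e4e3", 0.0)
        if name == "apoe2":
            return probs.get("e2e2", 0.0) + probs.get("e3e2", 0.0)
        raise KeyError(f"unknown factor {name!r}")

    def average_ptau_slope(self, fixed: Mapping[str, int] | None = None) -> float:
        """Population-average pTau217 slope, optionally fixing some factors.

        With factors independent of pTau217, the slope estimated in a
        (sub)population equals the base slope plus each offset weighted by
        that factor's frequency (or its fixed 0/1 level).
        """
        fixed = dict(fixed or {})
        slope = self.sni_model.ptau217_slope
        for f, off in self.sni_model.slope_offsets.items():
            level = fixed[f] if f in fixed else self.factor_prevalence(f)
            slope += off * level
        return slope


@dataclass(frozen=True)
class MegScenario:
    """Parameters for a MEG-like multichannel recording."""

    n_channels: int = 248
    sampling_rate: float = 1017.25  # Hz
    duration: float = 60.0  # seconds
    latent_corr: float | np.ndarray = 0.0
    ar_coefficients: tuple[float, ...] = ()
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be positive")
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise ValueError("sampling_rate and duration must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if np.isscalar(self.latent_corr):
            rho = float(self.latent_corr)
            if not (-1.0 < rho <= 1.0):
                raise ValueError("scalar latent_corr must lie in (-1, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.duration))


def default_cohort_scenario(**overrides) -> CohortScenario:
    """The default cohort preset; keyword overrides replace fields."""
    return replace(CohortScenario(), **overrides) if overrides else CohortScenario()


def default_meg_scenario(**overrides) -> MegScenario:
    """The default recording preset (248 channels, 60 s at 1017.25 Hz)."""
    return replace(MegScenario(), **overrides) if overrides else MegScenario()


@dataclass
class SimulatedCohort:
    """A generated cohort table together with its ground-truth scenario."""

    table: pd.DataFrame
    scenario: CohortScenario


_APOE_GROUP = {
    "e2e2": "ApoE2",
    "e3e2": "ApoE2",
    "e4e4": "ApoE4",
    "e4e3": "ApoE4",
    "e3e3": "other",
    "e2e4": "other",
}

COHORT_COLUMNS = (
    ["subject_id", "visit", "age", "moca"]
    + BIOMARKERS
    + ["apoe_group", "drb1_1301", "drb1_1302"]
    + VIRUSES
    + ["sni"]
)


def _factor_flag(name: str, apoe_group: str, flags: Mapping[str, int]) -> int:
    if name == "apoe4":
        return int(apoe_group == "ApoE4")
    if name == "apoe2":
        return int(apoe_group == "ApoE2")
    return int(flags[name])


def generate_cohort(scenario: CohortScenario, seed: int | None = None) -> SimulatedCohort:
    """Draw a repeated-visits cohort table from the scenario.

    One row per (subject, visit); visits are consecutive integers from 0 and
    ages advance by one year per visit.  Biomarkers are drawn log-normal with
    a common cross-biomarker correlation on the log scale, independently per
    visit.  SNI and MoCA are generated from the scenario's linear models
    *before* missingness is applied, so masked entries never distort the
    ground truth.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    n_bio = len(BIOMARKERS)
    log_cov = np.full((n_bio, n_bio), scenario.biomarker_log_corr, dtype=float)
    np.fill_diagonal(log_cov, 1.0)
    chol = np.linalg.cholesky(log_cov)
    mus = np.array([scenario.biomarker_params[b][0] for b in BIOMARKERS])
    sigmas = np.array([scenario.biomarker_params[b][1] for b in BIOMARKERS])

    weights = np.asarray(scenario.visit_weights, dtype=float)
    # acquisition-level mean visit index, used to centre first-visit age so
    # that the row-level age mean matches scenario.age_mean
    e_k = float(np.sum((np.arange(weights.size) + 1) * weights))
    e_cum = float(np.sum([(k * (k - 1) / 2) * w for k, w in zip(range(1, weights.size + 1), weights)]))
    baseline_age_mean = scenario.age_mean - e_cum / e_k

    genos = list(scenario.apoe_genotype_probs)
    geno_p = np.array([scenario.apoe_genotype_probs[g] for g in genos])

    sni_m, moca_m = scenario.sni_model, scenario.moca_model
    rows: list[dict] = []
    for s in range(scenario.n_subjects):
        n_visits = int(rng.choice(weights.size, p=weights)) + 1
        age0 = rng.normal(baseline_age_mean, scenario.age_sd)
        apoe_missing = rng.random() < scenario.apoe_missing_freq
        genotype = genos[int(rng.choice(len(genos), p=geno_p))]
        apoe_group = _APOE_GROUP[genotype]
        flags = {
            "drb1_1301": int(rng.random() < scenario.drb1_1301_freq),
            "drb1_1302": int(rng.random() < scenario.drb1_1302_freq),
        }
        for v in VIRUSES:
            flags[v] = int(rng.random() < scenario.sero_prevalence[v])
        u_sni = rng.normal(0.0, sni_m.subject_sd) if sni_m.subject_sd > 0 else 0.0
        u_moca = rng.normal(0.0, moca_m.subject_sd) if moca_m.subject_sd > 0 else 0.0

        slope = sni_m.ptau217_slope + sum(
            off * _factor_flag(f, apoe_group, flags) for f, off in sni_m.slope_offsets.items()
        )
        moca_slope = moca_m.ptau_sni_slope
        for f, q in moca_m.protection.items():
            moca_slope *= 1.0 - q * _factor_flag(f, apoe_group, flags)

        for v in range(n_visits):
            age = age0 + v
            logs = mus + sigmas * (chol @ rng.standard_normal(n_bio))
            bio = dict(zip(BIOMARKERS, np.exp(logs)))
            eps = rng.normal(0.0, sni_m.residual_sd) if sni_m.residual_sd > 0 else 0.0
            sni = sni_m.intercept + sni_m.age_slope * age + slope * bio["ptau217"] + u_sni + eps
            eps_m = rng.normal(0.0, moca_m.residual_sd) if moca_m.residual_sd > 0 else 0.0
            moca_raw = (
                moca_m.intercept
                + moca_m.age_slope * age
                + moca_slope * bio["ptau217"] * sni
                + u_moca
                + eps_m
            )
            moca = int(np.clip(round(moca_raw), 0, 30))
            row = {
                "subject_id": f"S{s:04d}",
                "visit": v,
                "age": age,
                "moca": moca,
                **bio,
                "apoe_group": pd.NA if apoe_missing else apoe_group,
                **{k: flags[k] for k in ("drb1_1301", "drb1_1302")},
                **{k: flags[k] for k in VIRUSES},
                "sni": sni,
            }
            rows.append(row)

    table = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    for col in ["drb1_1301", "drb1_1302"] + VIRUSES:
        table[col] = table[col].astype("Int64")
    # completely-at-random per-column missingness
    for col, rate in scenario.missingness_rates.items():
        if rate <= 0:
            continue
        mask = rng.random(len(table)) < rate
        table.loc[mask, col] = pd.NA if table[col].dtype == "Int64" else np.nan
    return SimulatedCohort(table=table, scenario=scenario)


def generate_meg(scenario: MegScenario, seed: int | None = None) -> MegRecording:
    """Draw a channels x samples recording with known correlation structure.

    A scalar ``latent_corr`` rho targets an equicorrelation matrix; a full
    matrix must be symmetric PSD with unit diagonal.  Channel mixing uses the
    symmetric eigendecomposition square root, so rho = 1 (duplicated
    channels) is handled exactly.  A non-empty ``ar_coefficients`` tuple
    applies the same AR recursion to every channel, which colors the spectra
    but leaves zero-lag cross-channel correlations unchanged in expectation.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    k, n = scenario.n_channels, scenario.n_samples

    if np.isscalar(scenario.latent_corr):
        rho = float(scenario.latent_corr)
        target = np.full((k, k), rho)
        np.fill_diagonal(target, 1.0)
    else:
        target = np.asarray(scenario.latent_corr, dtype=float)
        if target.shape != (k, k):
            raise ValueError("target correlation matrix shape must be (n_channels, n_channels)")
        if not np.allclose(target, target.T, atol=1e-10):
            raise ValueError("target correlation matrix must be symmetric")
        if not np.allclose(np.diag(target), 1.0, atol=1e-10):
            raise ValueError("target correlation matrix must have unit diagonal")

    evals, evecs = np.linalg.eigh(target)
    if np.min(evals) < -1e-8:
        raise ValueError("target correlation matrix is not positive semi-definite")
    root = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))
    data = root @ rng.standard_normal((k, n))

    if scenario.ar_coefficients:
        from scipy.signal import lfilter

        a = np.concatenate(([1.0], -np.asarray(scenario.ar_coefficients, dtype=float)))
        data = lfilter([1.0], a, data, axis=1)
    data *= scenario.noise_sd
    return MegRecording(data=data, sampling_rate=scenario.sampling_rate)


def write_cohort(cohort: SimulatedCohort | pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as CSV with missing values as empty fields."""
    table = cohort.table if isinstance(cohort, SimulatedCohort) else cohort
    table.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort`."""
    df = pd.read_csv(path)
    for col in ["drb1_1301", "drb1_1302"] + VIRUSES:
        if col in df.columns:
            df[col] = df[col].astype("Int64")
    return df


def _scenario_from_mapping(cls, mapping: Mapping) -> CohortScenario | MegScenario:
    mapping = dict(mapping)
    if cls is CohortScenario:
        if "sni_model" in mapping and isinstance(mapping["sni_model"], Mapping):
            mapping["sni_model"] = SniModel(**mapping["sni_model"])
        if "moca_model" in mapping and isinstance(mapping["moca_model"], Mapping):
            mapping["moca_model"] = MocaModel(**mapping["moca_model"])
        if "visit_weights" in mapping:
            mapping["visit_weights"] = tuple(mapping["visit_weights"])
    if cls is MegScenario:
        if "ar_coefficients" in mapping:
            mapping["ar_coefficients"] = tuple(mapping["ar_coefficients"])
        if isinstance(mapping.get("latent_corr"), list):
            mapping["latent_corr"] = np.asarray(mapping["latent_corr"], dtype=float)
    return cls(**mapping)


def load_cohort_scenario(path: str | Path) -> CohortScenario:
    """Load a cohort scenario from a YAML/JSON config file."""
    return _scenario_from_mapping(CohortScenario, yaml.safe_load(Path(path).read_text()) or {})


def load_meg_scenario(path: str | Path) -> MegScenario:
    """Load a recording scenario from a YAML/JSON config file."""
    return _scenario_from_mapping(MegScenario, yaml.safe_load(Path(path).read_text()) or {})
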