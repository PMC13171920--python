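"""Calibration and parameter-recovery simulation studies.

These functions run the full generate→analyze loop many times to check that
the pipeline is statistically calibrated: type-I error of the mixed-model
pTau217 term at the nominal level, 95% CI coverage of the stratified
moderation slopes, uniformity of the interaction p-value under the null, and
agreement of null per-pair Fisher-z values with their N(0, 1/(n-3)) sampling
distribution.  They back both the test suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from . import cohort as cohort_mod
from .sni import ArimaOrder, compute_sni
from .synthetic import (
    CohortScenario,
    MegScenario,
    SniModel,
    default_cohort_scenario,
    generate_cohort,
    generate_meg,
)

__all__ = [
    "null_scenario",
    "type_i_error",
    "null_interaction_pvalues",
    "slope_ci_coverage",
    "CoverageResult",
    "null_pair_z",
    "null_z_ks_test",
]


def null_scenario(n_subjects: int = 60, **overrides) -> CohortScenario:
    """A reduced-size scenario with no pTau217 effect and no moderation."""
    base = default_cohort_scenario(n_subjects=n_subjects, **overrides)
    return replace(base, sni_model=replace(base.sni_model, ptau217_slope=0.0, slope_offsets={}))


def type_i_error(
    n_replicates: int = 500,
    n_subjects: int = 60,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Empirical rejection rate of the pTau217 term under a true null.

    Each replicate generates a cohort with zero pTau217 effect and fits
    ``sni ~ age + ptau217`` with a subject random intercept; the reported
    rate should sit near ``alpha`` (binomial error applies).
    """
    rng = np.random.default_rng(seed)
    scen = null_scenario(n_subjects=n_subjects)
    rejections = 0
    pvals = []
    for _ in range(n_replicates):
        sim = generate_cohort(scen, seed=int(rng.integers(2**31)))
        fit = cohort_mod.fit_lmem(sim.table, "sni", covariates=["age", "ptau217"])
        p = fit.p("ptau217")
        pvals.append(p)
        rejections += p < alpha
    rate = rejections / n_replicates
    return {
        "rate": rate,
        "n_replicates": n_replicates,
        "alpha": alpha,
        "mc_se": float(np.sqrt(alpha * (1 - alpha) / n_replicates)),
        "pvalues": np.asarray(pvals),
    }


def null_interaction_pvalues(
    factor: str = "drb1_1301",
    n_replicates: int = 200,
    n_subjects: int = 80,
    seed: int = 0,
) -> np.ndarray:
    """Interaction-term p-values across replicates with no moderation effect.

    Under the null of parallel slopes these should be uniform on [0, 1].
    """
    rng = np.random.default_rng(seed)
    scen = null_scenario(n_subjects=n_subjects)
    # keep a nonzero base slope so the null concerns only the interaction
    scen = replace(scen, sni_model=replace(scen.sni_model, ptau217_slope=0.0015))
    out = []
    for _ in range(n_replicates):
        sim = generate_cohort(scen, seed=int(rng.integers(2**31)))
        res = cohort_mod.test_moderation(sim.table, factor)
        out.append(res.interaction_p)
    return np.asarray(out)


@dataclass
class CoverageResult:
    coverage_absent: float
    coverage_present: float
    coverage_overall: float
    n_replicates: int
    true_slope_absent: float
    true_slope_present: float


def slope_ci_coverage(
    n_replicates: int = 200,
    scenario: CohortScenario | None = None,
    factor: str = "drb1_1301",
    seed: int = 0,
    level: float = 0.95,
) -> CoverageResult:
    """95% CI coverage of the stratified pTau217 slopes across replicates.

    The default preset carries a negative DRB1*13:01 slope offset; each
    replicate runs the full moderation pipeline with forced stratification
    and checks whether each stratified slope CI (t-based, cluster-count df)
    covers the population-average slope of its stratum (base slope plus
    offsets weighted by the remaining factors' frequencies).
    """
    scen = default_cohort_scenario() if scenario is None else scenario
    truth = {lev: scen.average_ptau_slope(fixed={factor: lev}) for lev in (0, 1)}
    rng = np.random.default_rng(seed)
    cover = {0: 0, 1: 0}
    used = 0
    for _ in range(n_replicates):
        sim = generate_cohort(scen, seed=int(rng.integers(2**31)))
        res = cohort_mod.test_moderation(sim.table, factor, always_stratify=True)
        if res.stratified_fits is None:
            continue  # degenerate stratum in this replicate
        used += 1
        for lev in (0, 1):
            lo, hi = res.stratified_fits[lev].ci("ptau217", level=level)
            if lo <= truth[lev] <= hi:
                cover[lev] += 1
    if used == 0:
        raise RuntimeError("no replicate produced both stratified fits")
    return CoverageResult(
        coverage_absent=cover[0] / used,
        coverage_present=cover[1] / used,
        coverage_overall=(cover[0] + cover[1]) / (2 * used),
        n_replicates=used,
        true_slope_absent=truth[0],
        true_slope_present=truth[1],
    )


def null_pair_z(
    n_channels: int = 50,
    n_samples: int = 2000,
    seed: int = 0,
) -> tuple[np.ndarray, int]:
    """Per-pair Fisher-z values of an independent white-noise recording.

    With no prewhitening model (order (0,0,0)) the innovations are the raw
    demeaned channels, and each pair's z is approximately N(0, 1/(n-3)).
    """
    scen = MegScenario(
        n_channels=n_channels,
        sampling_rate=1000.0,
        duration=n_samples / 1000.0,
        latent_corr=0.0,
        seed=seed,
    )
    rec = generate_meg(scen)
    res = compute_sni(rec, order=ArimaOrder(0, 0, 0))
    return res.z, res.n_effective


def null_z_ks_test(n_channels: int = 50, n_samples: int = 2000, seed: int = 0) -> dict:
    """Kolmogorov-Smirnov test of null per-pair z against N(0, 1/(n-3))."""
    z, n_eff = null_pair_z(n_channels=n_channels, n_samples=n_samples, seed=seed)
    sd = 1.0 / np.sqrt(n_eff - 3)
    ks = stats.kstest(z, stats.norm(loc=0.0, scale=sd).cdf)
    return {
        "ks_stat": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "n_pairs": int(z.size),
        "n_effective": n_eff,
        "expected_sd": float(sd),
        "observed_sd": float(np.std(z)),
    }
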