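"""Sensitivity diagnostics for a two-sample MR analysis.

Covers the four standard checks: Cochran's Q and I-squared heterogeneity
(about the IVW fixed-effect estimate or the Egger fit), the Egger
intercept test for directional pleiotropy, the simulation-based residual
sum and outlier (MR-PRESSO) global and per-SNP tests, and leave-one-out
influence re-estimation under IVW.

Empirical p-values from the PRESSO simulations use the add-one rule
(1 + #{sim >= obs}) / (1 + n_sim), so a Monte-Carlo p is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .estimators import EggerIntercept, MREstimate, _egger_fit, ivw, mr_egger, wald_arrays
from .harmonize import HarmonizedSet


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with its df, chi-square p, and I-squared."""

    method: str  # "ivw" or "egger"
    q: float
    df: int
    pval: float
    i2: float


@dataclass(frozen=True)
class PressoResult:
    """MR-PRESSO global test and per-SNP outlier flags."""

    global_rss_obs: float
    global_pval: float
    outlier_snp_ids: list[str]
    per_snp_pvals: dict[str, float]
    n_sim: int
    seed: int


@dataclass(frozen=True)
class LeaveOneOutRow:
    omitted_snp_id: str
    estimate: MREstimate
    influential: bool


@dataclass(frozen=True)
class LeaveOneOutTable:
    rows: list[LeaveOneOutRow]
    full_estimate: MREstimate

    @property
    def influential_snp_ids(self) -> list[str]:
        return [r.omitted_snp_id for r in self.rows if r.influential]


@dataclass
class SensitivityReport:
    """Bundle of all diagnostics for one exposure -> outcome analysis."""

    q_ivw: HeterogeneityResult | None = None
    q_egger: HeterogeneityResult | None = None
    egger_intercept: EggerIntercept | None = None
    presso: PressoResult | None = None
    leave_one_out: LeaveOneOutTable | None = None
    notes: list[str] = field(default_factory=list)


def _pack_q(method: str, q: float, df: int) -> HeterogeneityResult:
    pval = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return HeterogeneityResult(method=method, q=float(q), df=int(df),
                               pval=min(max(pval, 5e-324), 1.0), i2=i2)


def cochran_q(hset: HarmonizedSet, reference: str = "ivw") -> HeterogeneityResult:
    """Heterogeneity of the per-SNP Wald ratios about a reference fit.

    ``ivw``: Q = sum w_j (theta_j - theta_ivw_fixed)^2 on J-1 df.
    ``egger``: Q = sum (beta_out_j - a - b*beta_exp_j)^2 / se_out_j^2 on J-2 df.
    """
    if reference == "ivw":
        theta, _, w = wald_arrays(hset)
        if theta.size < 2:
            raise ValueError("Cochran's Q (ivw) requires >= 2 instruments")
        beta = float(np.sum(w * theta) / w.sum())
        q = float(np.sum(w * (theta - beta) ** 2))
        return _pack_q("ivw", q, theta.size - 1)
    if reference == "egger":
        coef, _, j = _egger_fit(hset)
        bx, by, sy = hset.beta_exp, hset.beta_out, hset.se_out
        sign = np.where(bx < 0, -1.0, 1.0)
        resid = by * sign - coef[0] - coef[1] * (bx * sign)
        q = float(np.sum((resid / sy) ** 2))
        return _pack_q("egger", q, j - 2)
    raise ValueError(f"unknown reference {reference!r}")


def egger_intercept_test(hset: HarmonizedSet) -> EggerIntercept:
    """Two-sided t test (J-2 df) of the Egger intercept against zero."""
    return mr_egger(hset)[1]


def _loo_ivw_terms(w: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW estimates theta_(-j) for every j, in O(J)."""
    s1 = np.sum(w * theta)
    s0 = np.sum(w)
    return (s1 - w * theta) / (s0 - w)


def mr_presso(
    hset: HarmonizedSet,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_level: float = 0.05,
) -> PressoResult:
    """MR-PRESSO global residual-sum test and per-SNP outlier detection.

    The observed statistic is RSS = sum_j (beta_out_j - theta_(-j) *
    beta_exp_j)^2 / se_out_j^2 with theta_(-j) the IVW estimate excluding
    SNP j. The null distribution comes from ``n_sim`` parametric
    simulations drawing beta_exp* ~ N(beta_exp, se_exp) and beta_out* ~
    N(theta_(-j) * beta_exp, se_out) and recomputing the statistic. SNPs
    whose per-SNP residual p falls below ``outlier_level`` / J
    (Bonferroni) are flagged.
    """
    j = hset.n_snp
    if j < 4:
        raise ValueError("MR-PRESSO requires >= 4 instruments")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    if 1.0 / (n_sim + 1.0) >= outlier_level / j:
        import warnings

        warnings.warn(
            f"n_sim={n_sim} cannot resolve the Bonferroni outlier level "
            f"{outlier_level}/{j}; no SNP can be flagged",
            stacklevel=2,
        )
    bx, sx = hset.beta_exp, hset.se_exp
    by, sy = hset.beta_out, hset.se_out
    theta, _, w = wald_arrays(hset)
    theta_loo = _loo_ivw_terms(w, theta)
    resid_obs = (by - theta_loo * bx) ** 2 / sy**2
    rss_obs = float(resid_obs.sum())

    rng = np.random.default_rng(seed)
    bx_sim = rng.normal(bx[None, :], sx[None, :], size=(n_sim, j))
    by_sim = rng.normal(theta_loo[None, :] * bx[None, :], sy[None, :], size=(n_sim, j))
    theta_sim = by_sim / bx_sim
    w_sim = (bx_sim / sy[None, :]) ** 2
    s1 = np.sum(w_sim * theta_sim, axis=1, keepdims=True)
    s0 = np.sum(w_sim, axis=1, keepdims=True)
    theta_loo_sim = (s1 - w_sim * theta_sim) / (s0 - w_sim)
    resid_sim = (by_sim - theta_loo_sim * bx_sim) ** 2 / sy[None, :] ** 2
    rss_sim = resid_sim.sum(axis=1)

    global_pval = (1.0 + np.count_nonzero(rss_sim >= rss_obs)) / (n_sim + 1.0)
    per_snp = (1.0 + np.count_nonzero(resid_sim >= resid_obs[None, :], axis=0)) / (
        n_sim + 1.0
    )
    ids = hset.snp_ids
    per_snp_pvals = {ids[k]: float(per_snp[k]) for k in range(j)}
    cut = outlier_level / j
    outliers = [ids[k] for k in range(j) if per_snp[k] < cut]
    return PressoResult(
        global_rss_obs=rss_obs,
        global_pval=float(global_pval),
        outlier_snp_ids=outliers,
        per_snp_pvals=per_snp_pvals,
        n_sim=n_sim,
        seed=seed,
    )


def leave_one_out(
    hset: HarmonizedSet, effects_model: str = "multiplicative_random"
) -> LeaveOneOutTable:
    """IVW re-estimates omitting one SNP at a time.

    A row is marked influential when its confidence interval excludes the
    full-set point estimate.
    """
    j = hset.n_snp
    if j < 3:
        raise ValueError("leave-one-out requires >= 3 instruments")
    full = ivw(hset, effects_model)
    rows = []
    for k in range(j):
        sub = hset.subset([i for i in range(j) if i != k])
        est = ivw(sub, effects_model)
        influential = not (est.ci_low < full.beta < est.ci_high)
        rows.append(
            LeaveOneOutRow(
                omitted_snp_id=hset.pairs[k].snp_id, estimate=est, influential=influential
            )
        )
    return LeaveOneOutTable(rows=rows, full_estimate=full)


def run_sensitivity(
    hset: HarmonizedSet,
    presso_n_sim: int = 1000,
    presso_outlier_level: float = 0.05,
    seed: int = 0,
    run_presso: bool = True,
    effects_model: str = "multiplicative_random",
) -> SensitivityReport:
    """Run every diagnostic applicable at the available instrument count."""
    report = SensitivityReport()
    j = hset.n_snp
    if j >= 2:
        report.q_ivw = cochran_q(hset, "ivw")
    else:
        report.notes.append("q_ivw skipped: fewer than 2 instruments")
    if j >= 3:
        report.q_egger = cochran_q(hset, "egger")
        report.egger_intercept = egger_intercept_test(hset)
        report.leave_one_out = leave_one_out(hset, effects_model)
    else:
        report.notes.append("egger diagnostics skipped: fewer than 3 instruments")
    if run_presso and j >= 4:
        report.presso = mr_presso(
            hset, n_sim=presso_n_sim, seed=seed, outlier_level=presso_outlier_level
        )
    elif run_presso:
        report.notes.append("mr_presso skipped: fewer than 4 instruments")
    return report
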