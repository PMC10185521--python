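"""Causal-effect estimators for two-sample Mendelian randomization.

Every method combines per-SNP Wald ratios theta_j = beta_out_j / beta_exp_j,
with first-order delta-method standard errors se_j = se_out_j / |beta_exp_j|
(exposure-side noise ignored, the standard two-sample convention):

* **IVW** — inverse-variance-weighted mean of the Wald ratios, equivalent
  to zero-intercept weighted regression of outcome on exposure effects
  with weights 1/se_out^2. The default effects model is multiplicative
  random effects: the fixed-effect SE is inflated by
  max(1, sqrt(Q/(J-1))) where Q is Cochran's Q at the IVW estimate.
* **MR-Egger** — weighted regression with a free intercept after orienting
  every SNP to a positive exposure effect; the intercept estimates the
  average directional pleiotropy. SEs use multiplicative overdispersion
  floored at 1 and t-based inference on J-2 degrees of freedom.
* **Weighted median** — the weight-0.5 quantile of the ordered Wald
  ratios (linear interpolation across cumulative weights), consistent
  when valid instruments carry a majority of the weight. SE by parametric
  bootstrap.
* **Simple / weighted mode** — the mode of a normal-kernel density over
  the Wald ratios (ZEMPA-style mode-based estimation); bandwidth
  phi * 0.9 * min(sd, IQR/1.349) * J^(-1/5). SE by parametric bootstrap.

Binary-outcome effects are on the log-odds scale, so every estimate also
carries its exponentiated (odds-ratio) form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .harmonize import HarmonizedSet

Z95 = 1.959963984540054  # scipy.stats.norm.ppf(0.975)

METHOD_ORDER = ("egger", "weighted_median", "ivw", "simple_mode", "weighted_mode")

METHOD_LABELS = {
    "wald": "Wald ratio",
    "egger": "MR Egger",
    "weighted_median": "Weighted median",
    "ivw": "Inverse variance weighted",
    "simple_mode": "Simple mode",
    "weighted_mode": "Weighted mode",
}


class InsufficientInstrumentsError(ValueError):
    pass


class DegenerateInstrumentError(ValueError):
    pass


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate from one MR method."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def or_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_high(self) -> float:
        return math.exp(self.ci_high)


@dataclass(frozen=True)
class EggerIntercept:
    """MR-Egger intercept: the average directional pleiotropy per SNP."""

    intercept: float
    se: float
    pval: float


def wald_ratio(beta_exp: float, beta_out: float, se_out: float) -> tuple[float, float]:
    """Single-SNP causal estimate beta_out/beta_exp with its delta-method SE."""
    if beta_exp == 0:
        raise DegenerateInstrumentError("beta_exp = 0 gives an undefined Wald ratio")
    return beta_out / beta_exp, se_out / abs(beta_exp)


def wald_arrays(hset: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Wald ratios, their delta-method SEs, and IVW weights w = 1/se^2."""
    bx, by, sy = hset.beta_exp, hset.beta_out, hset.se_out
    if np.any(bx == 0):
        raise DegenerateInstrumentError("beta_exp = 0 gives an undefined Wald ratio")
    theta = by / bx
    se = sy / np.abs(bx)
    w = (bx / sy) ** 2
    return theta, se, w


def _package(method: str, beta: float, se: float, pval: float, n_snp: int,
             ci_mult: float = Z95) -> MREstimate:
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - ci_mult * se),
        ci_high=float(beta + ci_mult * se),
        pval=float(min(max(pval, 5e-324), 1.0)),
        n_snp=int(n_snp),
    )


def ivw(
    hset: HarmonizedSet, effects_model: str = "multiplicative_random"
) -> MREstimate:
    """Inverse-variance-weighted estimate over all instruments.

    ``effects_model``: ``fixed`` uses SE = (sum w)^(-1/2);
    ``multiplicative_random`` (default) inflates it by
    max(1, sqrt(Q/(J-1))), reducing to the fixed model when there is no
    excess heterogeneity.
    """
    if effects_model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown effects_model {effects_model!r}")
    theta, _, w = wald_arrays(hset)
    j = theta.size
    if j < 2:
        raise InsufficientInstrumentsError("IVW requires at least 2 instruments")
    sw = w.sum()
    beta = float(np.sum(w * theta) / sw)
    se = sw ** -0.5
    if effects_model == "multiplicative_random" and j > 1:
        q = float(np.sum(w * (theta - beta) ** 2))
        se *= max(1.0, math.sqrt(q / (j - 1)))
    z = beta / se
    pval = 2.0 * stats.norm.sf(abs(z))
    return _package("ivw", beta, se, pval, j)


def _egger_fit(hset: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, int]:
    """Weighted Egger regression; returns (coef, se, J) for [intercept, slope]."""
    bx, by, sy = hset.beta_exp, hset.beta_out, hset.se_out
    j = bx.size
    if j < 3:
        raise InsufficientInstrumentsError("MR-Egger requires at least 3 instruments")
    # orient every SNP to a positive exposure effect (Egger is not invariant
    # to per-SNP allele sign conventions)
    sign = np.where(bx < 0, -1.0, 1.0)
    x = bx * sign
    y = by * sign
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(j), x])
    A = X.T @ (w[:, None] * X)
    b = X.T @ (w * y)
    coef = np.linalg.solve(A, b)
    resid = y - X @ coef
    sigma2 = float(np.sum(w * resid**2) / (j - 2))
    cov = max(1.0, sigma2) * np.linalg.inv(A)
    return coef, np.sqrt(np.diag(cov)), j


def mr_egger(hset: HarmonizedSet) -> tuple[MREstimate, EggerIntercept]:
    """MR-Egger slope (causal effect) and intercept (directional pleiotropy)."""
    coef, se, j = _egger_fit(hset)
    df = j - 2
    tdist = stats.t(df)
    tcrit = float(tdist.ppf(0.975))
    p_slope = 2.0 * float(tdist.sf(abs(coef[1] / se[1])))
    p_int = 2.0 * float(tdist.sf(abs(coef[0] / se[0])))
    slope = _package("egger", coef[1], se[1], p_slope, j, ci_mult=tcrit)
    intercept = EggerIntercept(
        intercept=float(coef[0]), se=float(se[0]), pval=float(min(max(p_int, 5e-324), 1.0))
    )
    return slope, intercept


def _weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
    """Weight-0.5 quantile of theta, interpolating across cumulative weights."""
    order = np.argsort(theta, kind="stable")
    th = theta[order]
    p = w[order] / w.sum()
    s = np.cumsum(p) - 0.5 * p
    return float(np.interp(0.5, s, th))


def _weighted_median_rows(thetas: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise weighted median of a (B, J) matrix with shared weights."""
    order = np.argsort(thetas, axis=1, kind="stable")
    th = np.take_along_axis(thetas, order, axis=1)
    p = (w / w.sum())[None, :]
    p = np.take_along_axis(np.broadcast_to(p, thetas.shape).copy(), order, axis=1)
    s = np.cumsum(p, axis=1) - 0.5 * p
    b, j = thetas.shape
    idx = (s < 0.5).sum(axis=1)  # first cumulative point >= 0.5
    out = np.empty(b)
    lo = idx == 0
    hi = idx == j
    out[lo] = th[lo, 0]
    out[hi] = th[hi, -1]
    mid = ~(lo | hi)
    if np.any(mid):
        i = idx[mid]
        rows = np.nonzero(mid)[0]
        s0 = s[rows, i - 1]
        s1 = s[rows, i]
        t0 = th[rows, i - 1]
        t1 = th[rows, i]
        frac = np.where(s1 > s0, (0.5 - s0) / np.where(s1 > s0, s1 - s0, 1.0), 0.0)
        out[mid] = t0 + frac * (t1 - t0)
    return out


def _bootstrap_se(
    estimator, theta: np.ndarray, se_theta: np.ndarray, n_boot: int, seed: int
) -> float:
    """Parametric bootstrap: resample theta_j ~ N(theta_j, se_j^2), re-estimate."""
    rng = np.random.default_rng(seed)
    samples = rng.normal(theta[None, :], se_theta[None, :], size=(n_boot, theta.size))
    return float(np.std(estimator(samples), ddof=1))


def weighted_median(hset: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimate, consistent when valid instruments carry
    more than half the total weight."""
    theta, se_theta, w = wald_arrays(hset)
    if theta.size < 3:
        raise InsufficientInstrumentsError("weighted median requires >= 3 instruments")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    beta = _weighted_median(theta, w)
    se = _bootstrap_se(lambda t: _weighted_median_rows(t, w), theta, se_theta, n_boot, seed)
    z = beta / se if se > 0 else np.inf * np.sign(beta)
    pval = 2.0 * stats.norm.sf(abs(z)) if se > 0 else (1.0 if beta == 0 else 0.0)
    return _package("weighted_median", beta, se, pval, theta.size)


def _weighted_quantile(x: np.ndarray, p: np.ndarray, q: float) -> float:
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ps = p[order]
    s = np.cumsum(ps) - 0.5 * ps
    return float(np.interp(q, s, xs))


def _mode_bandwidth(theta: np.ndarray, p: np.ndarray, phi: float) -> float:
    j = theta.size
    mean = float(np.sum(p * theta))
    var = float(np.sum(p * (theta - mean) ** 2))
    sd = math.sqrt(var * j / max(j - 1, 1))  # small-sample correction
    iqr = _weighted_quantile(theta, p, 0.75) - _weighted_quantile(theta, p, 0.25)
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    return phi * 0.9 * spread * j ** (-1 / 5)


def _mode_point(thetas: np.ndarray, p: np.ndarray, h: float) -> np.ndarray:
    """Row-wise kernel-density mode over the theta_j evaluation grid."""
    diff = (thetas[:, :, None] - thetas[:, None, :]) / h
    dens = np.einsum("j,bij->bi", p, np.exp(-0.5 * diff**2))
    return thetas[np.arange(thetas.shape[0]), np.argmax(dens, axis=1)]


def mode_estimate(
    hset: HarmonizedSet,
    weighted: bool = False,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Mode-based estimate: the normal-kernel density mode of the Wald
    ratios, unweighted (simple mode) or with IVW weights (weighted mode)."""
    if phi <= 0:
        raise ValueError("phi must be > 0")
    theta, se_theta, w = wald_arrays(hset)
    j = theta.size
    if j < 3:
        raise InsufficientInstrumentsError("mode estimation requires >= 3 instruments")
    p = (w / w.sum()) if weighted else np.full(j, 1.0 / j)
    method = "weighted_mode" if weighted else "simple_mode"
    def est(samples: np.ndarray) -> np.ndarray:
        out = np.empty(samples.shape[0])
        # bandwidth is re-derived per replicate, as in mode-based estimation
        for i, row in enumerate(samples):
            hb = _mode_bandwidth(row, p, phi)
            # hb = 0 means all ratios identical: that value is the mode
            out[i] = row[0] if hb == 0 else _mode_point(row[None, :], p, hb)[0]
        return out

    beta = float(est(theta[None, :])[0])
    se = _bootstrap_se(est, theta, se_theta, n_boot, seed)
    z = beta / se if se > 0 else np.inf * np.sign(beta) if beta else 0.0
    pval = 2.0 * stats.norm.sf(abs(z)) if se > 0 else (1.0 if beta == 0 else 0.0)
    return _package(method, beta, se, pval, j)


def run_all_methods(
    hset: HarmonizedSet,
    effects_model: str = "multiplicative_random",
    n_boot: int = 1000,
    phi: float = 1.0,
    seed: int = 0,
) -> dict[str, MREstimate | None]:
    """All five estimates in the reporting order (Egger, weighted median,
    IVW, simple mode, weighted mode). A method whose instrument-count
    minimum is not met yields None rather than aborting the table; IVW is
    the designated primary method. A single-instrument set falls back to
    the Wald ratio under the ``ivw`` key."""
    out: dict[str, MREstimate | None] = {m: None for m in METHOD_ORDER}
    j = hset.n_snp
    if j == 1:
        p = hset.pairs[0]
        theta, se = wald_ratio(p.beta_exp, p.beta_out, p.se_out)
        pval = 2.0 * stats.norm.sf(abs(theta / se))
        out["ivw"] = _package("wald", theta, se, pval, 1)
        return out
    if j >= 2:
        out["ivw"] = ivw(hset, effects_model)
    if j >= 3:
        out["egger"] = mr_egger(hset)[0]
        out["weighted_median"] = weighted_median(hset, n_boot=n_boot, seed=seed)
        out["simple_mode"] = mode_estimate(
            hset, weighted=False, phi=phi, n_boot=n_boot, seed=seed + 1
        )
        out["weighted_mode"] = mode_estimate(
            hset, weighted=True, phi=phi, n_boot=n_boot, seed=seed + 2
        )
    return out
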