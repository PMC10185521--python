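"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the summary tables a two-sample MR analysis
consumes: per-SNP additive effects with standard errors consistent with
allele frequency and sample size, optional pleiotropic outcome effects,
palindromic allele pairs, strand-flipped or allele-swapped outcome
encodings, and non-significant background SNPs. Summary statistics are
simulated directly (no individual-level genotypes): for a variant with
effect-allele frequency ``eaf`` in a sample of ``n`` individuals the
sampling standard error of a standardized additive effect is

    se = 1 / sqrt(2 * eaf * (1 - eaf) * n),

the sampling-variance counterpart of the variance-explained formula
R^2 = 2*EAF*(1-EAF)*beta^2. Exposure and outcome noise are independent
(non-overlapping samples), matching the two-sample assumption.

True instrument effects are drawn as |N(0, exposure_effect_sd^2)| and
floored so each instrument's true F statistic reaches ``min_true_f``:
the effect allele is coded as the exposure-increasing allele, and every
instrument is genuinely strong, mirroring the instrument sets such
analyses retain after significance and weak-instrument screening.
Pleiotropic outcome effects a_j are drawn independently of the exposure
effects (the InSIDE condition holds by construction), directional when
``pleiotropy_mean`` is nonzero and balanced when it is zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .harmonize import COMPLEMENT
from .summary_io import SummaryDataset, SummaryRecord

_NONPALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                         ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimConfig:
    """Generating parameters of a synthetic two-sample MR dataset.

    Defaults mirror the study geometry the package targets: 15
    instruments for a serum-protein exposure measured in 21,758
    individuals against a binary outcome GWAS of 127,442 individuals,
    with no pleiotropy and no causal effect unless configured.
    """

    n_snps: int = 15
    n_exposure: int = 21_758
    n_outcome: int = 127_442
    theta: float = 0.0
    maf_range: tuple[float, float] = (0.1, 0.9)
    exposure_effect_sd: float = 0.15
    min_true_f: float = 80.0
    pleiotropy_prob: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    palindromic_fraction: float = 0.0
    palindromic_eaf_range: tuple[float, float] | None = None
    strand_flip_fraction: float = 0.0
    allele_swap_fraction: float = 0.0
    null_snp_count: int = 0
    id_offset: int = 100_001  # first synthetic rsID number
    seed: int = 0

    def validate(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        for name in ("pleiotropy_prob", "palindromic_fraction",
                     "strand_flip_fraction", "allele_swap_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"maf_range must satisfy 0 < low <= high < 1, got {self.maf_range}")
        if self.n_exposure < 3 or self.n_outcome < 3:
            raise ValueError("sample sizes must be >= 3")


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated dataset."""

    theta: float
    pleiotropic_snp_ids: list[str] = field(default_factory=list)
    palindromic_snp_ids: list[str] = field(default_factory=list)
    flipped_snp_ids: list[str] = field(default_factory=list)
    swapped_snp_ids: list[str] = field(default_factory=list)
    null_snp_ids: list[str] = field(default_factory=list)
    per_snp_true_effects: dict[str, float] = field(default_factory=dict)
    per_snp_pleiotropy: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _se_additive(eaf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)


def _pval_normal(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy import stats

    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, 5e-324, 1.0)


def simulate_pair(config: SimConfig) -> tuple[SummaryDataset, SummaryDataset, SimTruth]:
    """Generate matched exposure and outcome summary datasets plus truth.

    Identical configs (including the seed) produce identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    j = config.n_snps
    total = j + config.null_snp_count

    ids = [f"rs{config.id_offset + i}" for i in range(total)]
    is_instrument = np.zeros(total, dtype=bool)
    is_instrument[:j] = True

    # positions spaced far apart: a post-clumping world with no LD by default
    chrom = np.array([str(1 + (i % 22)) for i in range(total)])
    pos = np.array([1_000_000 + 10_000_000 * (i // 22) for i in range(total)])

    eaf = rng.uniform(config.maf_range[0], config.maf_range[1], size=total)

    # flagged palindromic instruments, optionally with a controlled EAF range
    n_pal = int(round(config.palindromic_fraction * j))
    pal_idx = rng.choice(j, size=n_pal, replace=False) if n_pal else np.array([], dtype=int)
    if config.palindromic_eaf_range is not None and n_pal:
        lo, hi = config.palindromic_eaf_range
        eaf[pal_idx] = rng.uniform(lo, hi, size=n_pal)

    # true exposure effects: positive (effect allele = exposure-increasing),
    # floored so every instrument's true F reaches min_true_f
    b = np.abs(rng.normal(0.0, config.exposure_effect_sd, size=total))
    r2_min = config.min_true_f / (config.n_exposure - 2 + config.min_true_f)
    b_floor = np.sqrt(r2_min / (2.0 * eaf * (1.0 - eaf)))
    b = np.maximum(b, b_floor)
    b[~is_instrument] = 0.0

    # pleiotropic outcome effects, independent of b (InSIDE by construction)
    pleio = np.zeros(total)
    pleio_mask = np.zeros(total, dtype=bool)
    if config.pleiotropy_prob > 0:
        pleio_mask[:j] = rng.random(j) < config.pleiotropy_prob
        pleio[pleio_mask] = rng.normal(
            config.pleiotropy_mean, config.pleiotropy_sd, size=int(pleio_mask.sum())
        )

    se_exp = _se_additive(eaf, config.n_exposure)
    se_out = _se_additive(eaf, config.n_outcome)
    beta_exp = b + rng.normal(0.0, se_exp)
    true_out = config.theta * b + pleio
    beta_out = true_out + rng.normal(0.0, se_out)

    # allele encodings
    pair_choice = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=total)
    ea = np.array([_NONPALINDROMIC_PAIRS[k][0] for k in pair_choice])
    oa = np.array([_NONPALINDROMIC_PAIRS[k][1] for k in pair_choice])
    if n_pal:
        pal_choice = rng.integers(0, len(_PALINDROMIC_PAIRS), size=n_pal)
        ea[pal_idx] = [_PALINDROMIC_PAIRS[k][0] for k in pal_choice]
        oa[pal_idx] = [_PALINDROMIC_PAIRS[k][1] for k in pal_choice]

    # outcome-side encodings: strand flips relabel alleles only; allele swaps
    # exchange the allele labels and transform the sign and EAF consistently
    flip_mask = np.zeros(total, dtype=bool)
    swap_mask = np.zeros(total, dtype=bool)
    nonpal = np.ones(total, dtype=bool)
    nonpal[pal_idx] = False
    candidates = np.flatnonzero(is_instrument & nonpal)
    n_flip = int(round(config.strand_flip_fraction * j))
    n_swap = int(round(config.allele_swap_fraction * j))
    shuffled = rng.permutation(candidates)
    flip_mask[shuffled[:n_flip]] = True
    swap_mask[shuffled[n_flip:n_flip + n_swap]] = True

    out_ea, out_oa = ea.copy(), oa.copy()
    out_beta = beta_out.copy()
    out_eaf = eaf.copy()
    for i in np.flatnonzero(flip_mask):
        out_ea[i] = COMPLEMENT[ea[i]]
        out_oa[i] = COMPLEMENT[oa[i]]
    for i in np.flatnonzero(swap_mask):
        out_ea[i], out_oa[i] = oa[i], ea[i]
        out_beta[i] = -out_beta[i]
        out_eaf[i] = 1.0 - out_eaf[i]

    def _records(id_list, chroms, poss, eas, oas, eafs, betas, ses, ns):
        pvals = _pval_normal(betas, ses)
        return [
            SummaryRecord(
                snp_id=id_list[i], chrom=chroms[i], pos=int(poss[i]),
                effect_allele=str(eas[i]), other_allele=str(oas[i]),
                eaf=float(eafs[i]), beta=float(betas[i]), se=float(ses[i]),
                pval=float(pvals[i]), n=int(ns),
            )
            for i in range(len(id_list))
        ]

    exposure = SummaryDataset(
        trait_id="sim-exposure",
        trait_type="continuous",
        records=_records(ids, chrom, pos, ea, oa, eaf, beta_exp, se_exp,
                         config.n_exposure),
    )
    outcome = SummaryDataset(
        trait_id="sim-outcome",
        trait_type="binary",
        records=_records(ids, chrom, pos, out_ea, out_oa, out_eaf, out_beta,
                         se_out, config.n_outcome),
    )
    truth = SimTruth(
        theta=config.theta,
        pleiotropic_snp_ids=[ids[i] for i in np.flatnonzero(pleio_mask)],
        palindromic_snp_ids=[ids[i] for i in sorted(pal_idx)],
        flipped_snp_ids=[ids[i] for i in np.flatnonzero(flip_mask)],
        swapped_snp_ids=[ids[i] for i in np.flatnonzero(swap_mask)],
        null_snp_ids=[ids[i] for i in np.flatnonzero(~is_instrument)],
        per_snp_true_effects={ids[i]: float(b[i]) for i in range(total)},
        per_snp_pleiotropy={ids[i]: float(pleio[i]) for i in range(total)},
        seed=config.seed,
    )
    return exposure, outcome, truth


def simulate_bidirectional(
    forward: SimConfig, reverse: SimConfig
) -> tuple[SummaryDataset, SummaryDataset, SimTruth, SimTruth]:
    """Two merged traits for a full bidirectional scenario.

    ``forward`` generates trait A's instruments and their effects on
    trait B (causal effect ``forward.theta``); ``reverse`` generates
    trait B's own instruments and their effects on A (causal effect
    ``reverse.theta``). The two instrument panels get disjoint rsIDs and
    are merged so each trait's dataset holds both its own instruments
    and the other trait's instrument lookups, as real GWAS pairs do.
    """
    if reverse.id_offset == forward.id_offset:
        from dataclasses import replace

        reverse = replace(
            reverse,
            id_offset=forward.id_offset + forward.n_snps + forward.null_snp_count,
        )
    a_exp, b_out, truth_fwd = simulate_pair(forward)
    b_exp, a_out, truth_rev = simulate_pair(reverse)

    def _merge(primary: SummaryDataset, extra: SummaryDataset, trait_id: str,
               trait_type: str) -> SummaryDataset:
        return SummaryDataset(
            trait_id=trait_id,
            trait_type=trait_type,
            records=list(primary.records) + list(extra.records),
        )

    # trait A plays the continuous (serum-protein) role, trait B the binary
    # (disease) role; reporting scale follows the outcome's trait type
    trait_a = _merge(a_exp, a_out, "sim-trait-a", "continuous")
    trait_b = _merge(b_exp, b_out, "sim-trait-b", "binary")
    return trait_a, trait_b, truth_fwd, truth_rev


def simulate_null_batch(
    config: SimConfig,
    n_reps: int,
    alpha: float = 0.05,
    palindrome_policy: str = "drop_intermediate",
) -> pd.DataFrame:
    """Repeated simulate-and-estimate runs for calibration and power studies.

    Each replicate draws a fresh dataset (seed ``config.seed + rep``),
    harmonizes it, and records the IVW, Egger and weighted-median
    estimates together with the IVW confidence interval, Cochran's Q p,
    and the Egger intercept p. With ``config.theta = 0`` the batch
    measures type-I error; with a nonzero theta it measures power, bias
    and coverage. Runs a light estimation path (no bootstrap SEs, no
    PRESSO) so thousand-replicate batches stay fast.
    """
    from dataclasses import replace

    from .estimators import _weighted_median, ivw, mr_egger, wald_arrays
    from .harmonize import harmonize_datasets
    from .instruments import instrument_stats, InstrumentSet
    from .sensitivity import cochran_q

    rows = []
    for rep in range(n_reps):
        cfg = replace(config, seed=int(config.seed + rep) % (2**31))
        exposure, outcome, truth = simulate_pair(cfg)
        iv = InstrumentSet(
            exposure_id=exposure.trait_id,
            members=[(rec, instrument_stats(rec)) for rec in exposure
                     if rec.snp_id not in set(truth.null_snp_ids)],
        )
        hset = harmonize_datasets(iv, outcome, palindrome_policy)
        est = ivw(hset)
        theta_arr, _, w = wald_arrays(hset)
        wm = _weighted_median(theta_arr, w)
        row = {
            "rep": rep,
            "n_snp": hset.n_snp,
            "theta_true": cfg.theta,
            "ivw_beta": est.beta,
            "ivw_se": est.se,
            "ivw_p": est.pval,
            "ivw_ci_low": est.ci_low,
            "ivw_ci_high": est.ci_high,
            "ivw_reject": est.pval < alpha,
            "ivw_covered": est.ci_low <= cfg.theta <= est.ci_high,
            "wm_beta": wm,
            "q_p": cochran_q(hset, "ivw").pval if hset.n_snp >= 2 else math.nan,
        }
        if hset.n_snp >= 3:
            slope, intercept = mr_egger(hset)
            row.update(
                egger_beta=slope.beta,
                egger_p=slope.pval,
                egger_intercept=intercept.intercept,
                egger_intercept_p=intercept.pval,
            )
        rows.append(row)
    return pd.DataFrame(rows)
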