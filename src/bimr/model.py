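"""Model/Results interface over the estimator and sensitivity layers.

`MRModel` holds one harmonized exposure -> outcome dataset; `fit()`
returns an `MRResults` carrying the five-method estimate table, the
sensitivity diagnostics, and a printable `summary()`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import MRConfig
from .estimators import (
    METHOD_LABELS,
    METHOD_ORDER,
    MREstimate,
    run_all_methods,
)
from .harmonize import HarmonizedSet, harmonize_datasets
from .instruments import select_instruments
from .sensitivity import SensitivityReport, run_sensitivity
from .summary_io import LDTable, SummaryDataset


class MRModel:
    """Two-sample Mendelian randomization model for one analysis direction.

    Parameters
    ----------
    harmonized
        Allele-aligned exposure/outcome effects (see
        :func:`bimr.harmonize.harmonize_datasets`).
    config
        Analysis thresholds; defaults to :class:`MRConfig`.

    Examples
    --------
    >>> from bimr import MRModel, SimConfig, simulate_pair
    >>> exposure, outcome, truth = simulate_pair(SimConfig(theta=0.1, seed=7))
    >>> results = MRModel.from_datasets(exposure, outcome).fit(seed=7)
    >>> round(results.estimates["ivw"].beta, 2)
    0.11
    """

    def __init__(self, harmonized: HarmonizedSet, config: MRConfig | None = None):
        self.harmonized = harmonized
        self.config = config or MRConfig()

    @classmethod
    def from_datasets(
        cls,
        exposure: SummaryDataset,
        outcome: SummaryDataset,
        ld: LDTable | None = None,
        excluded_ids: set[str] | None = None,
        config: MRConfig | None = None,
    ) -> "MRModel":
        """Select instruments from the exposure GWAS, harmonize against the
        outcome GWAS, and wrap the result as a model."""
        config = config or MRConfig()
        iv_set = select_instruments(
            exposure,
            ld=ld,
            excluded_ids=excluded_ids,
            p_threshold=config.p_threshold,
            clump_r2=config.clump_r2,
            clump_window_bp=config.clump_window_bp,
            f_min=config.f_min,
        )
        hset = harmonize_datasets(
            iv_set, outcome, config.palindrome_policy, config.eaf_window
        )
        model = cls(hset, config)
        model.instrument_set = iv_set
        return model

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        exposure_id: str = "exposure",
        outcome_id: str = "outcome",
        config: MRConfig | None = None,
    ) -> "MRModel":
        """Build a model from an already-harmonized effect table with
        columns ``beta_exp``, ``se_exp``, ``beta_out``, ``se_out`` and
        optionally ``snp_id``."""
        hset = HarmonizedSet.from_arrays(
            data["beta_exp"].to_numpy(),
            data["se_exp"].to_numpy(),
            data["beta_out"].to_numpy(),
            data["se_out"].to_numpy(),
            snp_ids=data["snp_id"].tolist() if "snp_id" in data else None,
            exposure_id=exposure_id,
            outcome_id=outcome_id,
        )
        return cls(hset, config)

    def fit(self, seed: int | None = None) -> "MRResults":
        """Run all five estimators and the sensitivity suite."""
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        estimates = run_all_methods(
            self.harmonized,
            effects_model=cfg.effects_model,
            n_boot=cfg.n_boot,
            phi=cfg.phi,
            seed=seed,
        )
        sensitivity = run_sensitivity(
            self.harmonized,
            presso_n_sim=cfg.presso_n_sim,
            presso_outlier_level=cfg.presso_outlier_level,
            seed=seed,
            run_presso=cfg.run_presso,
            effects_model=cfg.effects_model,
        )
        return MRResults(model=self, estimates=estimates, sensitivity=sensitivity)


@dataclass
class MRResults:
    """Fitted estimates and diagnostics for one MR analysis."""

    model: MRModel
    estimates: dict[str, MREstimate | None]
    sensitivity: SensitivityReport
    extras: dict = field(default_factory=dict)

    @property
    def primary(self) -> MREstimate | None:
        """The designated primary estimate (IVW; Wald ratio when J = 1)."""
        return self.estimates.get("ivw")

    @property
    def n_snp(self) -> int:
        return self.model.harmonized.n_snp

    def estimates_frame(self, or_scale: bool | None = None) -> pd.DataFrame:
        """Method table mirroring the standard reporting layout."""
        hset = self.model.harmonized
        if or_scale is None:
            or_scale = hset.outcome_trait_type == "binary"
        rows = []
        for method in METHOD_ORDER:
            est = self.estimates.get(method)
            if est is None:
                continue
            row = {
                "exposure": hset.exposure_id,
                "outcome": hset.outcome_id,
                "n_snp": est.n_snp,
                "method": METHOD_LABELS[est.method],
                "beta": est.beta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pval": est.pval,
            }
            if or_scale:
                row["or"] = est.or_
                row["or_low"] = est.or_low
                row["or_high"] = est.or_high
            rows.append(row)
        return pd.DataFrame(rows)

    def sensitivity_frame(self) -> pd.DataFrame:
        """One-row summary of the heterogeneity/pleiotropy/outlier checks."""
        s = self.sensitivity
        row = {
            "exposure": self.model.harmonized.exposure_id,
            "outcome": self.model.harmonized.outcome_id,
            "q_ivw": s.q_ivw.q if s.q_ivw else np.nan,
            "q_ivw_p": s.q_ivw.pval if s.q_ivw else np.nan,
            "i2": s.q_ivw.i2 if s.q_ivw else np.nan,
            "q_egger": s.q_egger.q if s.q_egger else np.nan,
            "q_egger_p": s.q_egger.pval if s.q_egger else np.nan,
            "egger_intercept": s.egger_intercept.intercept if s.egger_intercept else np.nan,
            "egger_intercept_p": s.egger_intercept.pval if s.egger_intercept else np.nan,
            "presso_global_p": s.presso.global_pval if s.presso else np.nan,
            "presso_outliers": ",".join(s.presso.outlier_snp_ids) if s.presso else "",
        }
        return pd.DataFrame([row])

    def leave_one_out_frame(self) -> pd.DataFrame:
        loo = self.sensitivity.leave_one_out
        if loo is None:
            return pd.DataFrame()
        rows = [
            {
                "omitted_snp_id": r.omitted_snp_id,
                "beta": r.estimate.beta,
                "se": r.estimate.se,
                "ci_low": r.estimate.ci_low,
                "ci_high": r.estimate.ci_high,
                "pval": r.estimate.pval,
                "influential": r.influential,
            }
            for r in loo.rows
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Printable report: estimate table plus diagnostics."""
        hset = self.model.harmonized
        or_scale = hset.outcome_trait_type == "binary"
        lines = [
            "Two-sample Mendelian randomization",
            f"  exposure: {hset.exposure_id}    outcome: {hset.outcome_id}",
            f"  instruments: {hset.n_snp} (removed during harmonization: {len(hset.removed)})",
            "",
        ]
        frame = self.estimates_frame(or_scale)
        if frame.empty:
            lines.append("  no estimates available")
        else:
            disp = frame.copy()
            if or_scale:
                disp["OR (95% CI)"] = [
                    f"{r['or']:.2f} ({r['or_low']:.2f}-{r['or_high']:.2f})"
                    for _, r in disp.iterrows()
                ]
                cols = ["method", "n_snp", "OR (95% CI)", "pval"]
            else:
                disp["beta (95% CI)"] = [
                    f"{r.beta:.3f} ({r.ci_low:.3f}-{r.ci_high:.3f})"
                    for r in disp.itertuples()
                ]
                cols = ["method", "n_snp", "beta (95% CI)", "pval"]
            disp["pval"] = [f"{p:.3g}" for p in disp["pval"]]
            lines.append(disp[cols].to_string(index=False))
        s = self.sensitivity
        lines.append("")
        if s.q_ivw:
            lines.append(
                f"  Cochran's Q (IVW): {s.q_ivw.q:.2f} on {s.q_ivw.df} df, "
                f"p = {s.q_ivw.pval:.3g}, I2 = {100 * s.q_ivw.i2:.1f}%"
            )
        if s.egger_intercept:
            lines.append(
                f"  Egger intercept: {s.egger_intercept.intercept:.4f} "
                f"(p = {s.egger_intercept.pval:.3g})"
            )
        if s.presso:
            outl = ", ".join(s.presso.outlier_snp_ids) or "none"
            lines.append(
                f"  MR-PRESSO global p = {s.presso.global_pval:.3g}; outliers: {outl}"
            )
        if s.leave_one_out:
            infl = ", ".join(s.leave_one_out.influential_snp_ids) or "none"
            lines.append(f"  Leave-one-out influential SNPs: {infl}")
        return "\n".join(lines)
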