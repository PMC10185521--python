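"""Orchestration of the bidirectional analysis and report rendering.

``run_direction`` executes the full chain for one exposure -> outcome
analysis (selection, harmonization, five estimators, sensitivity suite)
with the five-instrument gate; ``run_bidirectional`` runs both
directions independently, redoing instrument selection from scratch per
direction. ``render_report`` writes the per-analysis tables and a
combined JSON summary with deterministic content.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

from .config import MRConfig
from .harmonize import EmptyHarmonizationError, harmonize_datasets
from .instruments import check_min_instruments, select_instruments
from .model import MRModel, MRResults
from .summary_io import LDTable, SummaryDataset


@dataclass(frozen=True)
class SignificanceTier:
    """Evidence tier of a p-value under the Bonferroni policy."""

    tier: str  # "strong" | "suggestive" | "null"
    threshold_strong: float
    threshold_suggestive: float


@dataclass
class DirectionResult:
    """Everything produced for one exposure -> outcome analysis."""

    exposure_id: str
    outcome_id: str
    skipped: bool = False
    skip_reason: str = ""
    results: MRResults | None = None
    iv_audit: list = field(default_factory=list)
    n_instruments: int = 0
    n_harmonized: int = 0
    removed_in_harmonization: list = field(default_factory=list)
    seed: int = 0


def classify_significance(
    pval: float,
    n_tests: int,
    alpha: float = 0.05,
    suggestive_alpha: float = 0.05,
) -> SignificanceTier:
    """Bonferroni tiering: p < alpha/n_tests is strong evidence, p in
    [alpha/n_tests, suggestive_alpha) is suggestive, otherwise null."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    strong = alpha / n_tests
    if pval < strong:
        tier = "strong"
    elif pval < suggestive_alpha:
        tier = "suggestive"
    else:
        tier = "null"
    return SignificanceTier(
        tier=tier, threshold_strong=strong, threshold_suggestive=suggestive_alpha
    )


def derive_seed(master_seed: int, exposure_id: str, outcome_id: str) -> int:
    """Stable per-analysis seed below 2^31 derived from the master seed."""
    tag = f"{exposure_id}->{outcome_id}".encode()
    return (int(master_seed) ^ zlib.crc32(tag)) % (2**31)


def run_direction(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    ld: LDTable | None = None,
    excluded_ids: set[str] | None = None,
    config: MRConfig | None = None,
) -> DirectionResult:
    """One full exposure -> outcome analysis with the instrument gate.

    Analyses with fewer than ``config.min_snps`` selected instruments,
    or with no instrument surviving harmonization, return a skipped
    result with the reason instead of raising.
    """
    config = config or MRConfig()
    seed = derive_seed(config.seed, exposure.trait_id, outcome.trait_id)
    out = DirectionResult(
        exposure_id=exposure.trait_id, outcome_id=outcome.trait_id, seed=seed
    )
    iv_set = select_instruments(
        exposure,
        ld=ld,
        excluded_ids=excluded_ids,
        p_threshold=config.p_threshold,
        clump_r2=config.clump_r2,
        clump_window_bp=config.clump_window_bp,
        f_min=config.f_min,
    )
    out.iv_audit = iv_set.audit
    out.n_instruments = len(iv_set)
    if not check_min_instruments(iv_set, config.min_snps):
        out.skipped = True
        out.skip_reason = (
            f"fewer than {config.min_snps} instruments ({len(iv_set)} selected)"
        )
        return out
    try:
        hset = harmonize_datasets(
            iv_set, outcome, config.palindrome_policy, config.eaf_window
        )
    except EmptyHarmonizationError as exc:
        out.skipped = True
        out.skip_reason = str(exc)
        return out
    out.n_harmonized = hset.n_snp
    out.removed_in_harmonization = [(sid, reason.value) for sid, reason in hset.removed]
    model = MRModel(hset, config)
    out.results = model.fit(seed=seed)
    return out


def run_bidirectional(
    trait_a: SummaryDataset,
    trait_b: SummaryDataset,
    ld: LDTable | None = None,
    excluded_ids: set[str] | None = None,
    config: MRConfig | None = None,
) -> tuple[DirectionResult, DirectionResult]:
    """Both directions, each with instrument selection redone from scratch."""
    forward = run_direction(trait_a, trait_b, ld, excluded_ids, config)
    reverse = run_direction(trait_b, trait_a, ld, excluded_ids, config)
    return forward, reverse


def _direction_summary(res: DirectionResult, config: MRConfig, n_tests: int) -> dict:
    entry: dict = {
        "exposure": res.exposure_id,
        "outcome": res.outcome_id,
        "skipped": res.skipped,
        "n_instruments": res.n_instruments,
        "seed": res.seed,
    }
    if res.skipped:
        entry["skip_reason"] = res.skip_reason
        return entry
    assert res.results is not None
    entry["n_harmonized"] = res.n_harmonized
    entry["removed_in_harmonization"] = res.removed_in_harmonization
    estimates = {}
    for method, est in res.results.estimates.items():
        if est is None:
            continue
        estimates[method] = {
            "beta": est.beta,
            "se": est.se,
            "ci_low": est.ci_low,
            "ci_high": est.ci_high,
            "or": est.or_,
            "or_low": est.or_low,
            "or_high": est.or_high,
            "pval": est.pval,
            "n_snp": est.n_snp,
        }
    entry["estimates"] = estimates
    primary = res.results.primary
    if primary is not None:
        tier = classify_significance(
            primary.pval, n_tests, config.alpha, config.suggestive_alpha
        )
        entry["primary_tier"] = tier.tier
        entry["threshold_strong"] = tier.threshold_strong
    sens = res.results.sensitivity_frame().iloc[0].to_dict()
    sens.pop("exposure"), sens.pop("outcome")
    entry["sensitivity"] = {
        k: (v if isinstance(v, str) else (None if v != v else float(v)))
        for k, v in sens.items()
    }
    return entry


def render_report(
    results: list[DirectionResult],
    out_dir: str | Path,
    config: MRConfig | None = None,
) -> None:
    """Write per-analysis TSVs plus a combined, deterministic summary.json.

    For each completed analysis: ``methods.tsv`` (five-method table),
    ``sensitivity.tsv``, ``loo.tsv`` (leave-one-out), ``audit.tsv``.
    Skipped analyses appear in summary.json with their reason only.
    """
    config = config or MRConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_tests = config.n_tests or max(1, len(results))
    summary = {"n_tests": n_tests, "analyses": []}
    for res in results:
        summary["analyses"].append(_direction_summary(res, config, n_tests))
        if res.skipped:
            continue
        assert res.results is not None
        tag = f"{res.exposure_id}__{res.outcome_id}".replace("/", "_")
        sub = out_dir / tag
        sub.mkdir(exist_ok=True)
        res.results.estimates_frame().to_csv(sub / "methods.tsv", sep="\t", index=False)
        res.results.sensitivity_frame().to_csv(
            sub / "sensitivity.tsv", sep="\t", index=False
        )
        res.results.leave_one_out_frame().to_csv(sub / "loo.tsv", sep="\t", index=False)
        with open(sub / "audit.tsv", "w") as fh:
            fh.write("snp_id\tstage\treason\n")
            for entry in res.iv_audit:
                fh.write(f"{entry.snp_id}\t{entry.stage}\t{entry.reason}\n")
            for snp_id, reason in res.removed_in_harmonization:
                fh.write(f"{snp_id}\tharmonize\t{reason}\n")
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
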