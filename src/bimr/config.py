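"""Analysis configuration: every tunable threshold in one place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class MRConfig:
    """Thresholds and options for a bidirectional MR analysis.

    Defaults follow common two-sample MR practice: genome-wide
    significance 5e-8, LD clumping at r-squared < 0.01 within 5 Mb,
    weak-instrument cut F < 10, a five-instrument minimum per analysis,
    and a Bonferroni-corrected strong-evidence threshold alpha/n_tests
    with (alpha/n_tests, suggestive_alpha) treated as suggestive.
    """

    # instrument selection
    p_threshold: float = 5e-8
    clump_r2: float = 0.01
    clump_window_bp: int = 5_000_000
    f_min: float = 10.0
    min_snps: int = 5
    # harmonization
    palindrome_policy: str = "drop_intermediate"
    eaf_window: tuple[float, float] = (0.42, 0.58)
    # estimation
    effects_model: str = "multiplicative_random"
    n_boot: int = 1000
    phi: float = 1.0
    # sensitivity
    run_presso: bool = True
    presso_n_sim: int = 1000
    presso_outlier_level: float = 0.05
    # multiple-testing policy; n_tests = None means "count the analyses run"
    alpha: float = 0.05
    suggestive_alpha: float = 0.05
    n_tests: int | None = None
    # master seed; per-analysis seeds are derived from it
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["eaf_window"] = list(self.eaf_window)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MRConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "eaf_window" in data:
            data["eaf_window"] = tuple(data["eaf_window"])
        return cls(**data)
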