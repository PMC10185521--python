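"""Instrument selection for an exposure trait.

The selection chain mirrors standard two-sample MR practice: genome-wide
significance filtering (p < 5e-8), removal of SNPs on a user-supplied
confounder exclusion list, greedy LD clumping (r-squared < 0.01 within a
5 Mb window, accepting by ascending p-value), and an instrument-strength
screen that removes SNPs with F < 10. Analyses with fewer than five
surviving instruments are gated out.

Instrument strength uses the variance explained by a SNP under
Hardy-Weinberg equilibrium,

    R^2 = 2 * EAF * (1 - EAF) * beta^2,

and the corresponding one-instrument F statistic

    F = (N - 2) * R^2 / (1 - R^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .summary_io import LDTable, SummaryDataset, SummaryRecord

DEFAULT_P_THRESHOLD = 5e-8
DEFAULT_CLUMP_R2 = 0.01
DEFAULT_CLUMP_WINDOW_BP = 5_000_000
DEFAULT_F_MIN = 10.0
DEFAULT_MIN_SNPS = 5


class WeakInstrumentError(ValueError):
    """Per-SNP variance explained reaches 1, making F undefined."""


@dataclass(frozen=True)
class InstrumentStats:
    """Per-instrument variance explained and F statistic."""

    snp_id: str
    r2: float
    f_stat: float


@dataclass
class AuditEntry:
    snp_id: str
    stage: str
    reason: str


@dataclass
class InstrumentSet:
    """Instruments retained for one exposure plus the removal audit."""

    exposure_id: str
    members: list[tuple[SummaryRecord, InstrumentStats]] = field(default_factory=list)
    audit: list[AuditEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)

    @property
    def records(self) -> list[SummaryRecord]:
        return [rec for rec, _ in self.members]

    @property
    def snp_ids(self) -> list[str]:
        return [rec.snp_id for rec, _ in self.members]

    def audit_counts(self) -> dict[str, int]:
        """Number of SNPs removed per (stage, reason)."""
        counts: dict[str, int] = {}
        for entry in self.audit:
            key = f"{entry.stage}:{entry.reason}"
            counts[key] = counts.get(key, 0) + 1
        return counts


def compute_r2(eaf: float, beta: float) -> float:
    """Variance in the exposure explained by one SNP: 2*EAF*(1-EAF)*beta^2."""
    if not (0.0 < eaf < 1.0):
        raise ValueError(f"eaf must lie in (0,1), got {eaf}")
    r2 = 2.0 * eaf * (1.0 - eaf) * beta * beta
    if r2 >= 1.0:
        raise WeakInstrumentError(f"r2 {r2} >= 1 makes the F statistic undefined")
    return r2


def compute_f(n: int, r2: float) -> float:
    """One-instrument F statistic: (N-2) * r2 / (1 - r2)."""
    if n < 3:
        raise ValueError(f"n must be >= 3, got {n}")
    if not (0.0 <= r2 < 1.0):
        raise ValueError(f"r2 must lie in [0,1), got {r2}")
    return (n - 2) * r2 / (1.0 - r2)


def instrument_stats(record: SummaryRecord) -> InstrumentStats:
    r2 = compute_r2(record.eaf, record.beta)
    return InstrumentStats(snp_id=record.snp_id, r2=r2, f_stat=compute_f(record.n, r2))


def select_significant(
    dataset: SummaryDataset, p_threshold: float = DEFAULT_P_THRESHOLD
) -> list[SummaryRecord]:
    """Records with p strictly below the threshold, input order preserved."""
    if not (0.0 < p_threshold < 1.0):
        raise ValueError(f"p_threshold must lie in (0,1), got {p_threshold}")
    return [r for r in dataset if r.pval < p_threshold]


def apply_exclusion_list(
    records: list[SummaryRecord],
    excluded_ids: set[str],
    audit: list[AuditEntry] | None = None,
) -> list[SummaryRecord]:
    """Drop records whose snp_id appears on the confounder exclusion list."""
    kept: list[SummaryRecord] = []
    for rec in records:
        if rec.snp_id in excluded_ids:
            if audit is not None:
                audit.append(AuditEntry(rec.snp_id, "exclusion", "confounder"))
        else:
            kept.append(rec)
    return kept


def ld_clump(
    records: list[SummaryRecord],
    ld: LDTable,
    r2_threshold: float = DEFAULT_CLUMP_R2,
    window_bp: int = DEFAULT_CLUMP_WINDOW_BP,
    audit: list[AuditEntry] | None = None,
) -> list[SummaryRecord]:
    """Greedy LD clumping by ascending p-value.

    A record is accepted iff every already-accepted record on the same
    chromosome within ``window_bp`` has pairwise r-squared below
    ``r2_threshold``. Pairs on different chromosomes or outside the window
    count as r2 = 0; within-window pairs absent from the table count as 0
    with a warning. Output is sorted by genomic position.
    """
    if not (0.0 < r2_threshold < 1.0):
        raise ValueError(f"r2_threshold must lie in (0,1), got {r2_threshold}")
    if window_bp <= 0:
        raise ValueError(f"window_bp must be > 0, got {window_bp}")
    accepted: list[SummaryRecord] = []
    for rec in sorted(records, key=lambda r: (r.pval, r.snp_id)):
        keep = True
        for other in accepted:
            if other.chrom != rec.chrom or abs(other.pos - rec.pos) > window_bp:
                continue
            if (rec.snp_id, other.snp_id) not in ld:
                warnings.warn(
                    f"LD for within-window pair ({rec.snp_id},{other.snp_id}) "
                    "missing; treated as r2=0",
                    stacklevel=2,
                )
                continue
            if ld.get(rec.snp_id, other.snp_id) >= r2_threshold:
                keep = False
                if audit is not None:
                    audit.append(
                        AuditEntry(rec.snp_id, "clump", f"ld_with_{other.snp_id}")
                    )
                break
        if keep:
            accepted.append(rec)
    return sorted(accepted, key=lambda r: (r.chrom, r.pos, r.snp_id))


def filter_weak(
    records_with_stats: list[tuple[SummaryRecord, InstrumentStats]],
    f_min: float = DEFAULT_F_MIN,
    exposure_id: str = "",
    audit: list[AuditEntry] | None = None,
) -> InstrumentSet:
    """Drop instruments with F strictly below ``f_min`` (F = f_min is kept)."""
    out = InstrumentSet(exposure_id=exposure_id, audit=list(audit or []))
    for rec, st in records_with_stats:
        if st.f_stat < f_min:
            out.audit.append(AuditEntry(rec.snp_id, "strength", "weak_instrument"))
        else:
            out.members.append((rec, st))
    return out


def check_min_instruments(iv_set: InstrumentSet, min_snps: int = DEFAULT_MIN_SNPS) -> bool:
    """True iff the set holds at least ``min_snps`` instruments."""
    return len(iv_set) >= min_snps


def select_instruments(
    dataset: SummaryDataset,
    ld: LDTable | None = None,
    excluded_ids: set[str] | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    clump_r2: float = DEFAULT_CLUMP_R2,
    clump_window_bp: int = DEFAULT_CLUMP_WINDOW_BP,
    f_min: float = DEFAULT_F_MIN,
) -> InstrumentSet:
    """Run the full selection chain and return the audited instrument set."""
    audit: list[AuditEntry] = []
    sig = select_significant(dataset, p_threshold)
    for rec in dataset:
        if rec.pval >= p_threshold:
            audit.append(AuditEntry(rec.snp_id, "significance", "not_genome_wide"))
    kept = apply_exclusion_list(sig, excluded_ids or set(), audit=audit)
    kept = ld_clump(kept, ld or LDTable(), clump_r2, clump_window_bp, audit=audit)
    with_stats = [(rec, instrument_stats(rec)) for rec in kept]
    return filter_weak(with_stats, f_min, exposure_id=dataset.trait_id, audit=audit)
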