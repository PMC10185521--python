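"""Reading, validating and writing GWAS summary-statistic and LD tables.

The canonical on-disk dialect is plain TSV with one row per SNP. A
``column_map`` lets arbitrary headers be ingested; rows violating the
record invariants are dropped and counted rather than aborting the read.
Only single-nucleotide biallelic variants are accepted: the palindrome
logic downstream is defined only for single bases.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from scipy import stats

VALID_ALLELES = frozenset("ACGT")

#: canonical column order of the on-disk TSV dialect
CANONICAL_COLUMNS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)


class SummaryFormatError(ValueError):
    """A summary-statistic or LD file does not match the expected format."""


class EmptyDatasetError(ValueError):
    """No valid rows survived validation."""


@dataclass(frozen=True)
class SummaryRecord:
    """One SNP's association with one trait.

    ``beta`` is the per-allele additive effect of ``effect_allele``:
    log-odds for binary traits, SD units for normalised continuous traits.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int

    def validation_errors(self) -> list[str]:
        """Return invariant violations (empty list when the record is valid)."""
        errs: list[str] = []
        if self.effect_allele not in VALID_ALLELES:
            errs.append(f"invalid effect_allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            errs.append(f"invalid other_allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            errs.append("effect_allele equals other_allele")
        if not (self.se > 0) or not math.isfinite(self.se):
            errs.append("se must be > 0")
        if not (0.0 < self.eaf < 1.0):
            errs.append("eaf must lie in (0,1)")
        if not (0.0 < self.pval <= 1.0):
            errs.append("pval must lie in (0,1]")
        if self.n < 3:
            errs.append("n must be >= 3")
        if self.pos < 1:
            errs.append("pos must be >= 1")
        if not math.isfinite(self.beta):
            errs.append("beta must be finite")
        return errs

    def is_valid(self) -> bool:
        return not self.validation_errors()

    def check_pval_consistency(self, orders: float = 2.0) -> bool:
        """True when the stored p agrees with the normal-approximation p
        from beta/se to within ``orders`` orders of magnitude."""
        if self.se <= 0:
            return False
        z = abs(self.beta) / self.se
        expected = 2.0 * stats.norm.sf(z)
        if expected <= 0.0 or self.pval <= 0.0:
            # both in deep-underflow territory: treat as consistent
            return expected <= 0.0 and self.pval < 1e-300
        return abs(math.log10(expected) - math.log10(self.pval)) <= orders


@dataclass
class SummaryDataset:
    """An ordered collection of :class:`SummaryRecord` for one trait."""

    trait_id: str
    trait_type: str  # "continuous" or "binary"
    records: list[SummaryRecord] = field(default_factory=list)
    #: audit of rows dropped during reading: list of (row_index, reason)
    dropped: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type must be continuous|binary, got {self.trait_type!r}")
        ids = [r.snp_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate snp_id in dataset {self.trait_id!r}")
        self._index = {r.snp_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SummaryRecord]:
        return iter(self.records)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def get(self, snp_id: str) -> SummaryRecord | None:
        return self._index.get(snp_id)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[getattr(r, c) for c in CANONICAL_COLUMNS] for r in self.records],
            columns=list(CANONICAL_COLUMNS),
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, trait_id: str, trait_type: str
    ) -> "SummaryDataset":
        records = [
            SummaryRecord(
                snp_id=str(row.snp_id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                effect_allele=str(row.effect_allele).upper(),
                other_allele=str(row.other_allele).upper(),
                eaf=float(row.eaf),
                beta=float(row.beta),
                se=float(row.se),
                pval=float(row.pval),
                n=int(row.n),
            )
            for row in frame.itertuples(index=False)
        ]
        return cls(trait_id=trait_id, trait_type=trait_type, records=records)


class LDTable:
    """Pairwise r-squared lookup keyed by unordered SNP-ID pairs.

    ``r2(x, x)`` is 1 by definition; absent pairs default to 0.
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None):
        self._pairs: dict[frozenset, float] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self.set(a, b, r2)

    def set(self, snp_a: str, snp_b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise SummaryFormatError(f"r2 {r2} outside [0,1] for pair ({snp_a},{snp_b})")
        if snp_a == snp_b:
            return
        key = frozenset((snp_a, snp_b))
        # duplicates keep the maximum (conservative for clumping)
        self._pairs[key] = max(r2, self._pairs.get(key, 0.0))

    def get(self, snp_a: str, snp_b: str, default: float = 0.0) -> float:
        if snp_a == snp_b:
            return 1.0
        return self._pairs.get(frozenset((snp_a, snp_b)), default)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return a == b or frozenset((a, b)) in self._pairs

    def __len__(self) -> int:
        return len(self._pairs)

    def items(self) -> Iterable[tuple[tuple[str, str], float]]:
        for key, r2 in self._pairs.items():
            a, b = sorted(key)
            yield (a, b), r2


def _format_float(x: float) -> str:
    # repr round-trips doubles exactly (shortest representation)
    return repr(float(x))


def read_summary_stats(
    path: str | Path,
    trait_id: str,
    trait_type: str,
    column_map: Mapping[str, str] | None = None,
) -> SummaryDataset:
    """Read a tab-separated summary-statistics table.

    Parameters
    ----------
    path
        TSV file with a header row.
    trait_id, trait_type
        Labels for the resulting dataset (``trait_type`` in
        ``{"continuous", "binary"}``).
    column_map
        Mapping from canonical field name (``snp_id``, ``chrom``, ``pos``,
        ``effect_allele``, ``other_allele``, ``eaf``, ``beta``, ``se``,
        ``pval``, ``n``) to the column header used in the file. Omitted
        fields are assumed to already use the canonical header.

    Rows violating the record invariants are dropped and recorded in the
    returned dataset's ``dropped`` audit; alleles are uppercased. A stored
    p-value inconsistent with beta/se by more than two orders of magnitude
    raises a warning, not a rejection.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    colmap = {c: c for c in CANONICAL_COLUMNS}
    if column_map:
        colmap.update(column_map)
    for canonical, header in colmap.items():
        if header not in table.columns:
            raise SummaryFormatError(
                f"column {header!r} (mapped to {canonical!r}) missing from {path}"
            )

    records: list[SummaryRecord] = []
    dropped: list[tuple[int, str]] = []
    seen: set[str] = set()
    for i in range(len(table)):
        raw = {c: table.iloc[i][colmap[c]] for c in CANONICAL_COLUMNS}
        try:
            rec = SummaryRecord(
                snp_id=str(raw["snp_id"]),
                chrom=str(raw["chrom"]),
                pos=int(float(raw["pos"])),
                effect_allele=str(raw["effect_allele"]).upper(),
                other_allele=str(raw["other_allele"]).upper(),
                eaf=float(raw["eaf"]),
                beta=float(raw["beta"]),
                se=float(raw["se"]),
                pval=float(raw["pval"]),
                n=int(float(raw["n"])),
            )
        except (TypeError, ValueError) as exc:
            dropped.append((i, f"unparseable: {exc}"))
            continue
        errs = rec.validation_errors()
        if errs:
            dropped.append((i, "; ".join(errs)))
            continue
        if rec.snp_id in seen:
            dropped.append((i, "duplicate snp_id"))
            continue
        if not rec.check_pval_consistency():
            warnings.warn(
                f"{rec.snp_id}: pval {rec.pval:g} inconsistent with beta/se "
                "under the normal approximation",
                stacklevel=2,
            )
        seen.add(rec.snp_id)
        records.append(rec)
    if not records:
        raise EmptyDatasetError(f"no valid rows in {path}")
    return SummaryDataset(
        trait_id=trait_id, trait_type=trait_type, records=records, dropped=dropped
    )


def write_summary_stats(dataset: SummaryDataset, path: str | Path) -> None:
    """Write a dataset as canonical TSV; inverse of :func:`read_summary_stats`."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for r in dataset.records:
            fh.write(
                "\t".join(
                    [
                        r.snp_id,
                        r.chrom,
                        str(r.pos),
                        r.effect_allele,
                        r.other_allele,
                        _format_float(r.eaf),
                        _format_float(r.beta),
                        _format_float(r.se),
                        _format_float(r.pval),
                        str(r.n),
                    ]
                )
                + "\n"
            )


def read_ld_table(path: str | Path) -> LDTable:
    """Read a pairwise LD table (TSV columns ``snp_a``, ``snp_b``, ``r2``).

    Duplicate pairs keep the maximum r-squared; values outside [0,1] are a
    format error. Compatible with ``plink --r2`` output reshaped to three
    columns.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype={"snp_a": str, "snp_b": str})
    for col in ("snp_a", "snp_b", "r2"):
        if col not in table.columns:
            raise SummaryFormatError(f"LD table {path} missing column {col!r}")
    ld = LDTable()
    for row in table.itertuples(index=False):
        r2 = float(row.r2)
        if not np.isfinite(r2) or not (0.0 <= r2 <= 1.0):
            raise SummaryFormatError(f"r2 {row.r2} outside [0,1] in {path}")
        ld.set(str(row.snp_a), str(row.snp_b), r2)
    return ld


def write_ld_table(ld: LDTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("snp_a\tsnp_b\tr2\n")
        for (a, b), r2 in sorted(ld.items()):
            fh.write(f"{a}\t{b}\t{_format_float(r2)}\n")


def read_exclusion_list(path: str | Path) -> set[str]:
    """Read a confounder-exclusion list: one snp_id per line, '#' comments."""
    out: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.add(line)
    return out
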