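"""Allele harmonization between exposure and outcome summary statistics.

Two-sample MR combines per-SNP effects estimated in different cohorts,
which may report the same variant with the alleles swapped or on the
opposite strand. Harmonization rewrites every outcome record so that its
effect refers to the exposure's effect allele. Palindromic variants
(A/T or C/G) cannot be strand-resolved from allele labels; they are
either dropped outright or, when their allele frequency is far from 0.5,
oriented by frequency agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .instruments import InstrumentSet
from .summary_io import SummaryDataset, SummaryRecord

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

DEFAULT_EAF_WINDOW = (0.42, 0.58)


class PalindromePolicy(str, Enum):
    DROP_ALL = "drop_all"
    DROP_INTERMEDIATE = "drop_intermediate"


class Action(str, Enum):
    NONE = "none"
    SIGN_FLIP = "sign_flip"
    STRAND_FLIP = "strand_flip"
    STRAND_FLIP_AND_SIGN = "strand_flip_and_sign"


class RemovalReason(str, Enum):
    PALINDROMIC = "palindromic"
    PALINDROMIC_INTERMEDIATE_EAF = "palindromic_intermediate_eaf"
    ALLELE_MISMATCH = "allele_mismatch"
    MISSING_IN_OUTCOME = "missing_in_outcome"


class EmptyHarmonizationError(ValueError):
    """No instrument survived harmonization."""


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is {A,T} or {C,G} (same on both strands)."""
    return {effect_allele, other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class HarmonizedPair:
    """One SNP's exposure and outcome effects aligned to a common allele."""

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float
    eaf_out: float
    action: Action


@dataclass
class HarmonizedSet:
    """Aligned exposure/outcome effects for one analysis direction."""

    exposure_id: str
    outcome_id: str
    pairs: list[HarmonizedPair] = field(default_factory=list)
    removed: list[tuple[str, RemovalReason]] = field(default_factory=list)
    outcome_trait_type: str = "binary"

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_snp(self) -> int:
        return len(self.pairs)

    @property
    def snp_ids(self) -> list[str]:
        return [p.snp_id for p in self.pairs]

    # array views used by the estimators
    @property
    def beta_exp(self) -> np.ndarray:
        return np.array([p.beta_exp for p in self.pairs], dtype=float)

    @property
    def se_exp(self) -> np.ndarray:
        return np.array([p.se_exp for p in self.pairs], dtype=float)

    @property
    def beta_out(self) -> np.ndarray:
        return np.array([p.beta_out for p in self.pairs], dtype=float)

    @property
    def se_out(self) -> np.ndarray:
        return np.array([p.se_out for p in self.pairs], dtype=float)

    def subset(self, keep: list[int]) -> "HarmonizedSet":
        return HarmonizedSet(
            exposure_id=self.exposure_id,
            outcome_id=self.outcome_id,
            pairs=[self.pairs[i] for i in keep],
            removed=[],
            outcome_trait_type=self.outcome_trait_type,
        )

    @classmethod
    def from_arrays(
        cls,
        beta_exp,
        se_exp,
        beta_out,
        se_out,
        snp_ids=None,
        exposure_id: str = "exposure",
        outcome_id: str = "outcome",
        outcome_trait_type: str = "binary",
    ) -> "HarmonizedSet":
        """Build a set directly from aligned effect arrays (already harmonized)."""
        beta_exp = np.asarray(beta_exp, dtype=float)
        se_exp = np.asarray(se_exp, dtype=float)
        beta_out = np.asarray(beta_out, dtype=float)
        se_out = np.asarray(se_out, dtype=float)
        if snp_ids is None:
            snp_ids = [f"snp{i + 1}" for i in range(beta_exp.size)]
        pairs = [
            HarmonizedPair(
                snp_id=str(snp_ids[i]),
                beta_exp=float(beta_exp[i]),
                se_exp=float(se_exp[i]),
                beta_out=float(beta_out[i]),
                se_out=float(se_out[i]),
                eaf_exp=0.5,
                eaf_out=0.5,
                action=Action.NONE,
            )
            for i in range(beta_exp.size)
        ]
        return cls(
            exposure_id=exposure_id,
            outcome_id=outcome_id,
            pairs=pairs,
            outcome_trait_type=outcome_trait_type,
        )


def _aligned_pair(
    exp: SummaryRecord, out: SummaryRecord, flip_sign: bool, strand_flipped: bool
) -> HarmonizedPair:
    if flip_sign and strand_flipped:
        action = Action.STRAND_FLIP_AND_SIGN
    elif flip_sign:
        action = Action.SIGN_FLIP
    elif strand_flipped:
        action = Action.STRAND_FLIP
    else:
        action = Action.NONE
    beta_out = -out.beta if flip_sign else out.beta
    eaf_out = 1.0 - out.eaf if flip_sign else out.eaf
    return HarmonizedPair(
        snp_id=exp.snp_id,
        beta_exp=exp.beta,
        se_exp=exp.se,
        beta_out=beta_out,
        se_out=out.se,
        eaf_exp=exp.eaf,
        eaf_out=eaf_out,
        action=action,
    )


def harmonize_pair(
    exp: SummaryRecord,
    out: SummaryRecord,
    palindrome_policy: PalindromePolicy | str = PalindromePolicy.DROP_INTERMEDIATE,
    eaf_window: tuple[float, float] = DEFAULT_EAF_WINDOW,
) -> HarmonizedPair | RemovalReason:
    """Align one outcome record to the exposure's effect allele.

    Returns the harmonized pair, or the removal reason when the SNP must
    be dropped (ambiguous palindrome or irreconcilable alleles).
    """
    if exp.snp_id != out.snp_id:
        raise ValueError(f"snp_id mismatch: {exp.snp_id} vs {out.snp_id}")
    policy = PalindromePolicy(palindrome_policy)

    if is_palindromic(exp.effect_allele, exp.other_allele):
        # Strand is uninformative: {A,T} and {C,G} complement to themselves.
        if {out.effect_allele, out.other_allele} != {exp.effect_allele, exp.other_allele}:
            return RemovalReason.ALLELE_MISMATCH
        if policy is PalindromePolicy.DROP_ALL:
            return RemovalReason.PALINDROMIC
        low, high = eaf_window
        if low <= exp.eaf <= high or low <= out.eaf <= high:
            return RemovalReason.PALINDROMIC_INTERMEDIATE_EAF
        # Orient by frequency agreement: both EAFs on the same side of 0.5.
        flip = (exp.eaf - 0.5) * (out.eaf - 0.5) < 0
        return _aligned_pair(exp, out, flip_sign=flip, strand_flipped=False)

    e_pair = (exp.effect_allele, exp.other_allele)
    o_pair = (out.effect_allele, out.other_allele)
    o_comp = (COMPLEMENT[out.effect_allele], COMPLEMENT[out.other_allele])
    if o_pair == e_pair:
        return _aligned_pair(exp, out, flip_sign=False, strand_flipped=False)
    if o_pair == e_pair[::-1]:
        return _aligned_pair(exp, out, flip_sign=True, strand_flipped=False)
    if o_comp == e_pair:
        return _aligned_pair(exp, out, flip_sign=False, strand_flipped=True)
    if o_comp == e_pair[::-1]:
        return _aligned_pair(exp, out, flip_sign=True, strand_flipped=True)
    return RemovalReason.ALLELE_MISMATCH


def harmonize_datasets(
    iv_set: InstrumentSet,
    outcome: SummaryDataset,
    palindrome_policy: PalindromePolicy | str = PalindromePolicy.DROP_INTERMEDIATE,
    eaf_window: tuple[float, float] = DEFAULT_EAF_WINDOW,
) -> HarmonizedSet:
    """Harmonize every instrument against the outcome dataset.

    Instruments absent from the outcome are dropped (no proxy lookup);
    every removal is recorded with its reason.
    """
    hset = HarmonizedSet(
        exposure_id=iv_set.exposure_id,
        outcome_id=outcome.trait_id,
        outcome_trait_type=outcome.trait_type,
    )
    for rec in iv_set.records:
        out_rec = outcome.get(rec.snp_id)
        if out_rec is None:
            hset.removed.append((rec.snp_id, RemovalReason.MISSING_IN_OUTCOME))
            continue
        result = harmonize_pair(rec, out_rec, palindrome_policy, eaf_window)
        if isinstance(result, RemovalReason):
            hset.removed.append((rec.snp_id, result))
        else:
            hset.pairs.append(result)
    if not hset.pairs:
        raise EmptyHarmonizationError(
            f"no instrument survived harmonization for "
            f"{iv_set.exposure_id} -> {outcome.trait_id}"
        )
    return hset
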