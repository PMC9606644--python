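"""Allele harmonization of exposure instruments against outcome records.

Two GWAS may report the same SNP with the effect allele on either side and
on either strand.  Harmonization aligns every outcome record to the
exposure's effect allele: identical alleles pass through, swapped alleles
negate the outcome beta (and reflect its frequency), strand complements
are corrected first, and palindromic SNPs (A/T, C/G) — whose alleles are
identical on both strands — are resolved by comparing effect-allele
frequencies, or dropped when either frequency is too close to 0.5 to be
informative.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd

from .gwas_io import AssociationSet
from .instruments import InstrumentSet

log = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default half-window around 0.5 inside which a palindrome's EAF is
#: considered uninformative (drop window [0.42, 0.58])
DEFAULT_MAF_AMBIGUITY = 0.08

KEPT_ACTIONS = ("aligned", "flipped", "strand-corrected")


def is_palindromic(a1: str, a2: str) -> bool:
    """A/T or C/G pairs read identically on both strands."""
    return COMPLEMENT.get(a1) == a2


@dataclass(frozen=True)
class HarmonizedPair:
    """One SNP with exposure and outcome effects on the same effect allele."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None
    eaf_out: float | None
    palindromic: bool
    action: str


@dataclass
class HarmonizedDataset:
    """Matched exposure/outcome pairs — the unit every estimator consumes."""

    pairs: tuple[HarmonizedPair, ...]
    exposure_name: str = ""
    outcome_name: str = ""
    audit: Counter = None
    dropped: tuple[tuple[str, str], ...] = ()  # (snp_id, reason)

    def __post_init__(self) -> None:
        self.pairs = tuple(self.pairs)
        if self.audit is None:
            self.audit = Counter(p.action for p in self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(p.snp_id for p in self.pairs)

    @property
    def beta_exp(self) -> np.ndarray:
        return np.array([p.beta_exp for p in self.pairs])

    @property
    def se_exp(self) -> np.ndarray:
        return np.array([p.se_exp for p in self.pairs])

    @property
    def beta_out(self) -> np.ndarray:
        return np.array([p.beta_out for p in self.pairs])

    @property
    def se_out(self) -> np.ndarray:
        return np.array([p.se_out for p in self.pairs])

    def drop(self, snp_id: str) -> "HarmonizedDataset":
        """A copy without ``snp_id`` (used by leave-one-out)."""
        return HarmonizedDataset(
            tuple(p for p in self.pairs if p.snp_id != snp_id),
            self.exposure_name,
            self.outcome_name,
        )

    @classmethod
    def from_arrays(
        cls,
        beta_exp,
        se_exp,
        beta_out,
        se_out,
        snp_ids=None,
        exposure_name: str = "exposure",
        outcome_name: str = "outcome",
    ) -> "HarmonizedDataset":
        """Build a dataset from already-aligned effect arrays.

        Convenience path for simulation studies and for users whose data
        were harmonized upstream; alleles are filled with a neutral A/G.
        """
        beta_exp = np.asarray(beta_exp, dtype=float)
        if snp_ids is None:
            snp_ids = [f"snp{i + 1}" for i in range(len(beta_exp))]
        pairs = tuple(
            HarmonizedPair(
                snp_id=str(s),
                effect_allele="A",
                other_allele="G",
                beta_exp=float(bx),
                se_exp=float(sx),
                beta_out=float(by),
                se_out=float(sy),
                eaf_exp=None,
                eaf_out=None,
                palindromic=False,
                action="aligned",
            )
            for s, bx, sx, by, sy in zip(snp_ids, beta_exp, se_exp, beta_out, se_out)
        )
        return cls(pairs, exposure_name, outcome_name)

    def to_frame(self) -> pd.DataFrame:
        cols = [f.name for f in dc_fields(HarmonizedPair)]
        return pd.DataFrame(
            [[getattr(p, c) for c in cols] for p in self.pairs], columns=cols
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   exposure_name: str = "", outcome_name: str = "") -> "HarmonizedDataset":
        pairs = tuple(
            HarmonizedPair(
                snp_id=str(row.snp_id),
                effect_allele=str(row.effect_allele),
                other_allele=str(row.other_allele),
                beta_exp=float(row.beta_exp),
                se_exp=float(row.se_exp),
                beta_out=float(row.beta_out),
                se_out=float(row.se_out),
                eaf_exp=None if pd.isna(row.eaf_exp) else float(row.eaf_exp),
                eaf_out=None if pd.isna(row.eaf_out) else float(row.eaf_out),
                palindromic=bool(row.palindromic),
                action=str(row.action),
            )
            for row in df.itertuples(index=False)
        )
        return cls(pairs, exposure_name, outcome_name)


def _match_alleles(exp_ea, exp_oa, out_ea, out_oa):
    """Classify the outcome encoding relative to the exposure encoding.

    Returns (flip_sign, action) or None when irreconcilable.  Strand
    complementing is attempted only after direct and swapped matching fail.
    """
    if (out_ea, out_oa) == (exp_ea, exp_oa):
        return False, "aligned"
    if (out_ea, out_oa) == (exp_oa, exp_ea):
        return True, "flipped"
    c_ea, c_oa = COMPLEMENT[out_ea], COMPLEMENT[out_oa]
    if (c_ea, c_oa) == (exp_ea, exp_oa):
        return False, "strand-corrected"
    if (c_ea, c_oa) == (exp_oa, exp_ea):
        return True, "strand-corrected"
    return None


def harmonize(
    instruments: InstrumentSet | AssociationSet,
    outcome: AssociationSet,
    maf_ambiguity: float = DEFAULT_MAF_AMBIGUITY,
) -> HarmonizedDataset:
    """Match instruments to outcome records and align effect alleles.

    Matching is by ``snp_id``.  For palindromic SNPs both effect-allele
    frequencies must lie outside ``[0.5 - maf_ambiguity, 0.5 + maf_ambiguity]``;
    the sign is then flipped when the frequencies point at opposite
    alleles.  Set ``maf_ambiguity = 0.5`` to drop all palindromes.

    Raises
    ------
    ValueError
        If no pair survives harmonization.
    """
    exp_set = instruments.records if isinstance(instruments, InstrumentSet) else instruments

    pairs: list[HarmonizedPair] = []
    dropped: list[tuple[str, str]] = []
    audit: Counter = Counter()

    for exp in exp_set:
        out = outcome.get(exp.snp_id)
        if out is None:
            dropped.append((exp.snp_id, "absent in outcome"))
            audit["dropped: absent in outcome"] += 1
            continue
        if (out.chrom != exp.chrom) or (out.pos != exp.pos):
            log.warning(
                "%s: chrom/pos disagree between exposure (%s:%d) and outcome "
                "(%s:%d); matching on snp_id", exp.snp_id, exp.chrom, exp.pos,
                out.chrom, out.pos,
            )

        beta_out, eaf_out = out.beta, out.eaf
        palindromic = is_palindromic(exp.effect_allele, exp.other_allele)

        if palindromic:
            if {out.effect_allele, out.other_allele} != {exp.effect_allele, exp.other_allele}:
                dropped.append((exp.snp_id, "irreconcilable alleles"))
                audit["dropped: irreconcilable alleles"] += 1
                continue
            if exp.eaf is None or eaf_out is None:
                dropped.append((exp.snp_id, "missing EAF"))
                audit["dropped: missing EAF"] += 1
                continue
            lo, hi = 0.5 - maf_ambiguity, 0.5 + maf_ambiguity
            if (lo <= exp.eaf <= hi) or (lo <= eaf_out <= hi):
                dropped.append((exp.snp_id, "ambiguous palindrome"))
                audit["dropped: ambiguous palindrome"] += 1
                continue
            # Frequencies on opposite sides of 0.5 indicate opposite alleles.
            if (exp.eaf - 0.5) * (eaf_out - 0.5) < 0:
                beta_out, eaf_out, action = -beta_out, 1.0 - eaf_out, "flipped"
            else:
                action = "aligned"
        else:
            matched = _match_alleles(
                exp.effect_allele, exp.other_allele, out.effect_allele, out.other_allele
            )
            if matched is None:
                dropped.append((exp.snp_id, "irreconcilable alleles"))
                audit["dropped: irreconcilable alleles"] += 1
                continue
            flip, action = matched
            if flip:
                beta_out = -beta_out
                eaf_out = None if eaf_out is None else 1.0 - eaf_out

        audit[action] += 1
        pairs.append(
            HarmonizedPair(
                snp_id=exp.snp_id,
                effect_allele=exp.effect_allele,
                other_allele=exp.other_allele,
                beta_exp=exp.beta,
                se_exp=exp.se,
                beta_out=beta_out,
                se_out=out.se,
                eaf_exp=exp.eaf,
                eaf_out=eaf_out,
                palindromic=palindromic,
                action=action,
            )
        )

    if not pairs:
        raise ValueError("no SNP pair survived harmonization")
    return HarmonizedDataset(
        tuple(pairs),
        exposure_name=exp_set.trait_name,
        outcome_name=outcome.trait_name,
        audit=audit,
        dropped=tuple(dropped),
    )
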