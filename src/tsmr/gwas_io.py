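"""Reading, validation, and writing of GWAS summary-statistic tables.

The on-disk dialect is headered text, tab-separated by default (comma is
also accepted), one row per variant.  Base-pair positions are 1-based, the
usual GWAS summary-statistics convention.  Missing values are written as
``NA``.  A configurable column map connects arbitrary source headers to the
canonical field names, so release-specific layouts can be read without
preprocessing.

Validation is conservative: rows violating a hard invariant are dropped,
counted, and attributed to exactly one rule (the first that fails, in a
fixed order); values are never silently altered beyond upper-casing
alleles.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: canonical field name -> default source column header
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "snp_id": "snp_id",
    "chrom": "chrom",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
    "trait": "trait",
}

MANDATORY_FIELDS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pval",
)
OPTIONAL_FIELDS = ("eaf", "n", "trait")

#: drop rules in attribution order; each dropped row is charged to the
#: first rule it violates.
DROP_RULES = (
    "missing mandatory value",
    "non-SNP variant",
    "identical alleles",
    "non-positive se",
    "invalid position",
    "EAF outside (0,1)",
    "p-value outside (0,1]",
)


@dataclass(frozen=True)
class SummaryRecord:
    """One SNP's association with one trait.

    ``beta`` is the per-effect-allele effect in trait SD units, ``se`` its
    standard error, ``eaf`` the effect-allele frequency (may be absent).
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: float | None = None
    trait: str | None = None


@dataclass
class AssociationSet:
    """An ordered collection of :class:`SummaryRecord` with unique ids.

    ``role`` is ``"exposure"`` or ``"outcome"``; ``drop_counts`` records,
    per validation rule, how many input rows were discarded when the set
    was read from disk.
    """

    records: tuple[SummaryRecord, ...]
    role: str = "exposure"
    trait_name: str = ""
    drop_counts: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        self.records = tuple(self.records)
        ids = [r.snp_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate snp_id values: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SummaryRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SummaryRecord:
        return self.records[i]

    def ids(self) -> tuple[str, ...]:
        return tuple(r.snp_id for r in self.records)

    def get(self, snp_id: str) -> SummaryRecord | None:
        return self._index().get(snp_id)

    def _index(self) -> dict[str, SummaryRecord]:
        if not hasattr(self, "_idx") or len(self._idx) != len(self.records):
            self._idx = {r.snp_id: r for r in self.records}
        return self._idx

    def restrict(self, keep_ids) -> "AssociationSet":
        """Subset to ``keep_ids``, preserving the original record order."""
        keep = set(keep_ids)
        return AssociationSet(
            tuple(r for r in self.records if r.snp_id in keep),
            role=self.role,
            trait_name=self.trait_name,
        )

    def to_frame(self) -> pd.DataFrame:
        cols = [f.name for f in dc_fields(SummaryRecord)]
        return pd.DataFrame(
            [[getattr(r, c) for c in cols] for r in self.records], columns=cols
        )


def _detect_delimiter(path: Path) -> str:
    with open(path, "r") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _validate(df: pd.DataFrame) -> tuple[pd.DataFrame, Counter]:
    """Partition rows into valid / dropped, attributing each drop to one rule."""
    n = len(df)
    reason = np.full(n, "", dtype=object)

    def charge(mask: np.ndarray, rule: str) -> None:
        mask = np.asarray(mask, dtype=bool) & (reason == "")
        reason[mask] = rule

    mandatory_missing = np.zeros(n, dtype=bool)
    for col in MANDATORY_FIELDS:
        mandatory_missing |= df[col].isna().to_numpy()
    charge(mandatory_missing, "missing mandatory value")

    ea = df["effect_allele"].astype("string").str.strip().str.upper()
    oa = df["other_allele"].astype("string").str.strip().str.upper()
    non_snp = ~(ea.isin(VALID_ALLELES) & oa.isin(VALID_ALLELES))
    charge(non_snp.fillna(True).to_numpy(), "non-SNP variant")
    charge((ea == oa).fillna(False).to_numpy(), "identical alleles")

    charge((df["se"] <= 0).fillna(False).to_numpy(), "non-positive se")
    charge((df["pos"] < 1).fillna(False).to_numpy(), "invalid position")
    if "eaf" in df:
        bad_eaf = ((df["eaf"] <= 0) | (df["eaf"] >= 1)) & df["eaf"].notna()
        charge(bad_eaf.to_numpy(), "EAF outside (0,1)")
    charge(((df["pval"] <= 0) | (df["pval"] > 1)).fillna(False).to_numpy(),
           "p-value outside (0,1]")

    keep = reason == ""
    counts = Counter(r for r in reason if r)
    valid = df.loc[keep].copy()
    valid["effect_allele"] = ea[keep]
    valid["other_allele"] = oa[keep]
    return valid, counts


def _warn_pval_consistency(df: pd.DataFrame) -> None:
    # Factor-of-2 agreement between the printed p and 2*Phi(-|beta/se|);
    # a warning only, since source files round aggressively.
    z = np.abs(df["beta"].to_numpy(dtype=float) / df["se"].to_numpy(dtype=float))
    expected = np.clip(2.0 * stats.norm.sf(z), 1e-300, 1.0)
    p = df["pval"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        ratio = p / expected
    inconsistent = (ratio > 2.0) | (ratio < 0.5)
    n_bad = int(inconsistent.sum())
    if n_bad:
        log.warning(
            "%d row(s) have p-values inconsistent with 2*Phi(-|beta/se|) "
            "beyond a factor of 2", n_bad,
        )


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    role: str = "exposure",
    trait_name: str | None = None,
) -> AssociationSet:
    """Read a GWAS summary-statistic table into an :class:`AssociationSet`.

    Parameters
    ----------
    path
        Tab- or comma-separated text file with a header row.
    column_map
        Mapping from canonical field names (``snp_id``, ``chrom``, ``pos``,
        ``effect_allele``, ``other_allele``, ``eaf``, ``beta``, ``se``,
        ``pval``, ``n``, ``trait``) to the source column headers.  Fields
        absent from the map fall back to the canonical name itself.
    role
        ``"exposure"`` or ``"outcome"``.
    trait_name
        Trait label for the set; defaults to the per-row ``trait`` column
        when present.

    Raises
    ------
    ValueError
        If a mandatory column is missing or no valid row survives.
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(
        path,
        sep=_detect_delimiter(path),
        dtype={cmap["snp_id"]: str, cmap["chrom"]: str,
               cmap["effect_allele"]: str, cmap["other_allele"]: str},
        na_values=["NA", "na", ""],
        float_precision="round_trip",
    )
    rename = {src: canon for canon, src in cmap.items() if src in raw.columns}
    df = raw.rename(columns=rename)

    missing = [f for f in MANDATORY_FIELDS if f not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    for f in OPTIONAL_FIELDS:
        if f not in df.columns:
            df[f] = pd.NA

    for col in ("pos", "beta", "se", "pval", "eaf", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    valid, counts = _validate(df)
    for rule, k in counts.items():
        log.info("%s: dropped %d row(s): %s", path.name, k, rule)
    if not len(valid):
        raise ValueError(f"{path}: zero valid rows after validation")
    _warn_pval_consistency(valid)

    records = tuple(
        SummaryRecord(
            snp_id=str(row.snp_id),
            chrom=str(row.chrom),
            pos=int(row.pos),
            effect_allele=str(row.effect_allele),
            other_allele=str(row.other_allele),
            beta=float(row.beta),
            se=float(row.se),
            pval=float(row.pval),
            eaf=None if pd.isna(row.eaf) else float(row.eaf),
            n=None if pd.isna(row.n) else float(row.n),
            trait=None if pd.isna(row.trait) else str(row.trait),
        )
        for row in valid.itertuples(index=False)
    )
    tname = trait_name or (records[0].trait or "")
    return AssociationSet(records, role=role, trait_name=tname,
                          drop_counts=counts)


def _roundtrip_floats(df: pd.DataFrame) -> pd.DataFrame:
    """Render float columns as shortest round-trip reprs (csv writers
    otherwise truncate the mantissa)."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f" or out[col].map(
            lambda v: isinstance(v, float)
        ).any():
            out[col] = out[col].map(
                lambda v: repr(float(v)) if isinstance(v, float) and not pd.isna(v) else v
            )
    return out


def write_summary_stats(aset: AssociationSet, path: str | Path) -> None:
    """Write an :class:`AssociationSet` as headered, tab-separated text.

    Floats are written with shortest round-trip representation, so
    ``read_summary_stats`` recovers them exactly.
    """
    if not len(aset):
        raise ValueError("refusing to write an empty AssociationSet")
    _roundtrip_floats(aset.to_frame()).to_csv(path, sep="\t", index=False, na_rep="NA")


# --- harmonized-dataset serialization (the pipeline's central intermediate) ---

def write_harmonized(dataset, path: str | Path) -> None:
    """Serialize a :class:`tsmr.harmonize.HarmonizedDataset` as TSV."""
    _roundtrip_floats(dataset.to_frame()).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_harmonized(path: str | Path):
    """Read a harmonized dataset written by :func:`write_harmonized`."""
    from .harmonize import HarmonizedDataset

    df = pd.read_csv(path, sep="\t", na_values=["NA", ""],
                     float_precision="round_trip")
    return HarmonizedDataset.from_frame(df)
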