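"""Instrument selection from an exposure association set.

Selection follows the conventional two-sample MR order: genome-wide
significance filter (p < 5e-8), greedy distance/LD clumping, exclusion of
confounder-associated SNPs via a static blacklist, and removal of weak
instruments by the per-SNP F statistic (F = beta^2 / se^2, drop F <= 10).

Clumping works against an explicit, user-supplied r^2 matrix; when none is
given it degrades to distance-only clumping with a logged warning.  No
reference-panel LD computation is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .gwas_io import AssociationSet, SummaryRecord  # noqa: F401  (re-exported)

log = logging.getLogger(__name__)


def _chrom_key(chrom: str):
    """Sort chromosomes numerically where possible (1..22 before X, Y)."""
    c = str(chrom).removeprefix("chr")
    return (0, int(c), "") if c.isdigit() else (1, 0, c)


@dataclass
class ClumpConfig:
    """Thresholds for instrument pruning.

    ``window_kb`` is the exclusion radius around each index SNP;
    ``ld`` an optional symmetric matrix of pairwise r^2 (snp_id-labelled
    pandas DataFrame).
    """

    p_threshold: float = 5.0e-8
    window_kb: float = 5000.0
    r2_threshold: float = 0.001
    ld: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold <= 1.0:
            raise ValueError("p_threshold must be in (0, 1]")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be > 0")
        if not 0.0 <= self.r2_threshold <= 1.0:
            raise ValueError("r2_threshold must be in [0, 1]")
        if self.ld is not None:
            m = self.ld.to_numpy(dtype=float)
            if m.shape[0] != m.shape[1] or list(self.ld.index) != list(self.ld.columns):
                raise ValueError("ld matrix must be square with matching labels")
            if not np.allclose(m, m.T, atol=1e-8):
                raise ValueError("ld matrix must be symmetric")
            if not np.allclose(np.diag(m), 1.0, atol=1e-6):
                raise ValueError("ld matrix must have unit diagonal")


@dataclass
class InstrumentSet:
    """Selected instruments plus their per-SNP F statistics."""

    records: AssociationSet
    f_stats: np.ndarray
    provenance: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.f_stats = np.asarray(self.f_stats, dtype=float)
        if len(self.f_stats) != len(self.records):
            raise ValueError("f_stats length must equal record count")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def mean_f(self) -> float:
        return float(np.mean(self.f_stats)) if len(self) else float("nan")


def filter_by_pvalue(aset: AssociationSet, p_threshold: float = 5.0e-8) -> AssociationSet:
    """Keep SNPs with association p-value below ``p_threshold`` (order kept)."""
    kept = tuple(r for r in aset if r.pval < p_threshold)
    if not kept:
        log.warning("significance filter at p < %g retained no SNPs", p_threshold)
    return AssociationSet(kept, role=aset.role, trait_name=aset.trait_name)


def clump(aset: AssociationSet, config: ClumpConfig) -> AssociationSet:
    """Greedy clumping: repeatedly promote the most significant unclumped SNP.

    The index SNP removes every other SNP on the same chromosome within
    ``window_kb`` and, when an r^2 matrix is supplied, every SNP anywhere
    with r^2 >= ``r2_threshold`` against it.  Ties on p-value break by
    (chromosome, position, snp_id), so the output is order-independent and
    needs no seed.  Index SNPs are returned sorted by chromosome, position.
    """
    if config.ld is not None:
        known = set(config.ld.index)
        for r in aset:
            if r.snp_id not in known:
                raise KeyError(f"ld matrix is missing snp_id {r.snp_id!r}")
    else:
        log.warning("no LD matrix supplied; clumping is distance-only")

    window_bp = config.window_kb * 1000.0
    remaining = {r.snp_id: r for r in aset}
    index_snps: list[SummaryRecord] = []
    while remaining:
        idx = min(
            remaining.values(),
            key=lambda r: (r.pval, _chrom_key(r.chrom), r.pos, r.snp_id),
        )
        index_snps.append(idx)
        del remaining[idx.snp_id]
        victims = []
        for r in remaining.values():
            if r.chrom == idx.chrom and abs(r.pos - idx.pos) <= window_bp:
                victims.append(r.snp_id)
            elif config.ld is not None and (
                config.ld.at[idx.snp_id, r.snp_id] >= config.r2_threshold
            ):
                victims.append(r.snp_id)
        for v in victims:
            del remaining[v]
    index_snps.sort(key=lambda r: (_chrom_key(r.chrom), r.pos, r.snp_id))
    return AssociationSet(tuple(index_snps), role=aset.role, trait_name=aset.trait_name)


def exclude_snps(
    aset: AssociationSet, blacklist: Iterable[str], reason: str = "confounder-associated"
) -> AssociationSet:
    """Remove blacklisted SNP ids, logging each removal with ``reason``."""
    black = set(blacklist)
    present = black & set(aset.ids())
    for snp in sorted(present):
        log.info("excluding %s: %s", snp, reason)
    for snp in sorted(black - present):
        log.info("blacklisted id %s absent from set; no-op", snp)
    kept = tuple(r for r in aset if r.snp_id not in black)
    return AssociationSet(kept, role=aset.role, trait_name=aset.trait_name)


def f_statistic(beta, se):
    """Per-instrument strength, F = beta^2 / se^2.  Requires se > 0."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    out = (beta / se) ** 2
    return float(out) if out.ndim == 0 else out


def filter_by_f(
    aset: AssociationSet,
    min_f: float = 10.0,
    provenance: Mapping[str, tuple[str, ...]] | None = None,
) -> InstrumentSet:
    """Drop weak instruments (F <= ``min_f``; strict F > ``min_f`` kept)."""
    fvals = {r.snp_id: f_statistic(r.beta, r.se) for r in aset}
    kept = tuple(r for r in aset if fvals[r.snp_id] > min_f)
    if not kept:
        log.warning("F filter at F > %g retained no SNPs", min_f)
    records = AssociationSet(kept, role=aset.role, trait_name=aset.trait_name)
    prov = {
        r.snp_id: tuple(provenance.get(r.snp_id, ())) + ("f_filter",)
        if provenance
        else ("f_filter",)
        for r in kept
    }
    return InstrumentSet(records, np.array([fvals[r.snp_id] for r in kept]), prov)


def read_blacklist(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (snp_id, reason) confounder blacklist."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        out[parts[0]] = parts[1] if len(parts) > 1 else "blacklisted"
    return out


def read_ld_matrix(path: str | Path) -> pd.DataFrame:
    """Read a square r^2 matrix TSV with snp_id header row and column."""
    return pd.read_csv(path, sep="\t", index_col=0)
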