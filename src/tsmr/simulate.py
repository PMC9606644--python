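"""Synthetic two-sample GWAS summary statistics with known causal structure.

The generator emulates the statistical shape of two non-overlapping GWAS —
an exposure study and an outcome study — sharing a panel of independent
SNPs.  For SNP j:

* allele frequency maf_j ~ Uniform(maf_range);
* true SNP-exposure effect gamma_j ~ Normal(0, gamma_sd^2), in exposure-SD
  units per effect allele;
* a direct (pleiotropic) SNP-outcome effect for a fraction
  ``prop_invalid`` of SNPs, drawn in the exposure-increasing allele frame
  as a_j ~ Normal(alpha_mean·s_j, alpha_sd^2) with s_j = ±1 under
  "balanced" and s_j = +1 under "directional", then mapped back to the
  recorded allele frame (alpha_j = sign(gamma_j)·a_j);
* true outcome effect Gamma_j = theta·gamma_j + alpha_j;
* standard errors from the usual summary-statistic approximation
  se = 1/sqrt(2·maf·(1-maf)·n), tying instrument strength to sample size;
* observed effects drawn independently around the truths (two samples, no
  overlap), p-values from the normal.

Allele metadata exercise harmonization: a configurable fraction of SNPs is
palindromic (A/T or C/G), and the outcome re-encodes SNPs by swapping the
allele labels (negating its beta) and/or reporting the opposite strand.
Outcome allele frequencies get small cohort noise.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import AssociationSet, SummaryRecord, write_summary_stats
from .harmonize import COMPLEMENT
from .instruments import f_statistic

PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))
NON_PALINDROMIC_PAIRS = (
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
)

PLEIOTROPY_REGIMES = ("none", "balanced", "directional")


@dataclass
class SimulationConfig:
    """Generating parameters for one simulated two-sample study.

    Defaults describe a well-powered study: 70 independent instruments, a
    protective causal effect of -0.2 SD outcome per SD exposure, exposure
    GWAS of 200,000 and outcome GWAS of 60,000 individuals, and
    SNP-exposure effects (gamma_sd = 0.025 SD) that put the typical
    instrument F statistic near 50.  Pleiotropy regimes give 30% of SNPs
    direct outcome effects with mean 0.03 SD — large enough that the
    per-instrument pleiotropic ratio shift dwarfs the ratio sampling noise,
    the regime the robust estimators are designed for.
    """

    n_snp: int = 70
    theta: float = -0.2
    gamma_sd: float = 0.025
    pleiotropy: str = "none"
    alpha_mean: float = 0.03
    alpha_sd: float = 0.01
    prop_invalid: float = 0.3
    n_exposure: int = 200_000
    n_outcome: int = 60_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    palindromic_frac: float = 0.1
    swap_frac: float = 0.25
    strand_flip_frac: float = 0.2
    eaf_noise_sd: float = 0.005
    ld_block_size: int = 1
    ld_block_r2: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snp < 1:
            raise ValueError("n_snp must be >= 1")
        if self.pleiotropy not in PLEIOTROPY_REGIMES:
            raise ValueError(f"pleiotropy must be one of {PLEIOTROPY_REGIMES}")
        if not 0.0 <= self.prop_invalid <= 1.0:
            raise ValueError("prop_invalid must be in [0, 1]")
        if self.n_exposure < 100 or self.n_outcome < 100:
            raise ValueError("sample sizes must be >= 100")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.gamma_sd <= 0:
            raise ValueError("gamma_sd must be > 0")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")


@dataclass
class SimulationTruth:
    """Generating parameters paired with the realized per-SNP truths."""

    theta: float
    gamma: tuple[float, ...]
    alpha: tuple[float, ...]
    invalid_ids: tuple[str, ...]
    seed: int
    snp_ids: tuple[str, ...] = ()
    ld: pd.DataFrame | None = field(default=None, repr=False)

    def to_json_dict(self) -> dict:
        d = {
            "theta": self.theta,
            "gamma": list(self.gamma),
            "alpha": list(self.alpha),
            "invalid_ids": list(self.invalid_ids),
            "seed": self.seed,
            "snp_ids": list(self.snp_ids),
        }
        return d


def _se_from_maf(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _pval(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return np.clip(2.0 * stats.norm.sf(np.abs(beta) / se), 1e-300, 1.0)


def _positions(cfg: SimulationConfig, rng: np.random.Generator):
    """Deterministic, widely spaced placements: independent by construction.

    With ``ld_block_size > 1`` consecutive SNPs form tight blocks (10 kb
    spacing within, one block per slot) sharing an r^2 of ``ld_block_r2``.
    """
    n = cfg.n_snp
    chroms, positions = [], []
    block = cfg.ld_block_size
    for j in range(n):
        slot = j // block
        within = j % block
        chroms.append(str(slot % 22 + 1))
        positions.append(10_000_000 + (slot // 22) * 20_000_000 + within * 10_000)
    return chroms, positions


def _ld_matrix(cfg: SimulationConfig, snp_ids) -> pd.DataFrame | None:
    if cfg.ld_block_size <= 1:
        return None
    n = len(snp_ids)
    m = np.eye(n)
    for j in range(n):
        for k in range(n):
            if j != k and j // cfg.ld_block_size == k // cfg.ld_block_size:
                m[j, k] = cfg.ld_block_r2
    return pd.DataFrame(m, index=snp_ids, columns=snp_ids)


def simulate_two_sample(
    config: SimulationConfig,
) -> tuple[AssociationSet, AssociationSet, SimulationTruth]:
    """Draw one exposure/outcome summary-statistic pair plus its truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snp
    snp_ids = [f"rs{1000 + j}" for j in range(n)]
    chroms, positions = _positions(cfg, rng)

    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], n)
    gamma = rng.normal(0.0, cfg.gamma_sd, n)

    alpha = np.zeros(n)
    invalid = np.zeros(n, dtype=bool)
    if cfg.pleiotropy != "none" and cfg.prop_invalid > 0:
        n_inv = int(round(cfg.prop_invalid * n))
        inv_idx = rng.choice(n, size=n_inv, replace=False)
        invalid[inv_idx] = True
        s = rng.choice([-1.0, 1.0], size=n_inv) if cfg.pleiotropy == "balanced" else np.ones(n_inv)
        a_oriented = rng.normal(cfg.alpha_mean * s, cfg.alpha_sd)
        # map from the exposure-increasing frame back to the recorded allele
        alpha[inv_idx] = np.sign(gamma[inv_idx]) * a_oriented
    big_gamma = cfg.theta * gamma + alpha

    se_exp = _se_from_maf(maf, cfg.n_exposure)
    se_out = _se_from_maf(maf, cfg.n_outcome)
    beta_exp = rng.normal(gamma, se_exp)
    beta_out = rng.normal(big_gamma, se_out)
    p_exp = _pval(beta_exp, se_exp)
    p_out = _pval(beta_out, se_out)

    is_pal = rng.random(n) < cfg.palindromic_frac
    pal_choice = rng.integers(0, len(PALINDROMIC_PAIRS), n)
    npal_choice = rng.integers(0, len(NON_PALINDROMIC_PAIRS), n)
    eaf_exp = np.where(rng.random(n) < 0.5, maf, 1.0 - maf)
    eaf_out_true = np.clip(
        eaf_exp + rng.normal(0.0, cfg.eaf_noise_sd, n), 0.01, 0.99
    )
    swap = rng.random(n) < cfg.swap_frac
    strand = rng.random(n) < cfg.strand_flip_frac

    exp_records, out_records = [], []
    for j in range(n):
        ea, oa = (
            PALINDROMIC_PAIRS[pal_choice[j]]
            if is_pal[j]
            else NON_PALINDROMIC_PAIRS[npal_choice[j]]
        )
        exp_records.append(
            SummaryRecord(
                snp_id=snp_ids[j], chrom=chroms[j], pos=positions[j],
                effect_allele=ea, other_allele=oa, beta=float(beta_exp[j]),
                se=float(se_exp[j]), pval=float(p_exp[j]),
                eaf=float(eaf_exp[j]), n=float(cfg.n_exposure),
                trait="synthetic_exposure",
            )
        )
        o_ea, o_oa, o_beta, o_eaf = ea, oa, float(beta_out[j]), float(eaf_out_true[j])
        if swap[j]:
            o_ea, o_oa = o_oa, o_ea
            o_beta, o_eaf = -o_beta, 1.0 - o_eaf
        if strand[j]:
            o_ea, o_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]
        out_records.append(
            SummaryRecord(
                snp_id=snp_ids[j], chrom=chroms[j], pos=positions[j],
                effect_allele=o_ea, other_allele=o_oa, beta=o_beta,
                se=float(se_out[j]), pval=float(p_out[j]),
                eaf=o_eaf, n=float(cfg.n_outcome),
                trait="synthetic_outcome",
            )
        )

    truth = SimulationTruth(
        theta=cfg.theta,
        gamma=tuple(float(g) for g in gamma),
        alpha=tuple(float(a) for a in alpha),
        invalid_ids=tuple(snp_ids[j] for j in range(n) if invalid[j]),
        seed=cfg.seed,
        snp_ids=tuple(snp_ids),
        ld=_ld_matrix(cfg, snp_ids),
    )
    exposure = AssociationSet(tuple(exp_records), role="exposure",
                              trait_name="synthetic_exposure")
    outcome = AssociationSet(tuple(out_records), role="outcome",
                             trait_name="synthetic_outcome")
    return exposure, outcome, truth


#: the standard test scenarios; each entry overrides the config defaults
SCENARIOS: dict[str, dict] = {
    "null": {"theta": 0.0},
    "reference_study": {"theta": -0.2, "n_snp": 66},
    "balanced_pleiotropy": {"theta": -0.2, "pleiotropy": "balanced", "alpha_mean": 0.0},
    "directional_pleiotropy": {"theta": -0.2, "pleiotropy": "directional"},
    "median_robustness": {"theta": -0.2, "pleiotropy": "directional", "prop_invalid": 0.4},
    "weak_instruments": {"theta": -0.2, "gamma_sd": 0.004},
}


def make_fixture_suite(out_dir: str | Path, seed: int = 0) -> dict[str, dict[str, Path]]:
    """Write the standard scenario suite as TSV pairs plus truth JSON.

    Returns ``{scenario: {"exposure": path, "outcome": path, "truth": path}}``.
    Each truth file also records ``n_weak_instruments``, the count of SNPs
    with F <= 10 recomputed from the written exposure table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suite: dict[str, dict[str, Path]] = {}
    for k, (name, overrides) in enumerate(SCENARIOS.items()):
        child_seed = (seed * 1009 + 7919 * k) % (2**31)
        cfg = SimulationConfig(seed=child_seed, **overrides)
        exposure, outcome, truth = simulate_two_sample(cfg)
        paths = {
            "exposure": out_dir / f"{name}.exposure.tsv",
            "outcome": out_dir / f"{name}.outcome.tsv",
            "truth": out_dir / f"{name}.truth.json",
        }
        write_summary_stats(exposure, paths["exposure"])
        write_summary_stats(outcome, paths["outcome"])
        f = np.array([f_statistic(r.beta, r.se) for r in exposure])
        doc = truth.to_json_dict()
        doc["scenario"] = name
        doc["config"] = {kk: vv for kk, vv in asdict(cfg).items()}
        doc["n_weak_instruments"] = int(np.sum(f <= 10.0))
        paths["truth"].write_text(json.dumps(doc, indent=1))
        suite[name] = paths
    return suite
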