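"""End-to-end orchestration: selection → clumping → exclusion → F filter →
harmonization → five estimators → sensitivity suite → reports.

The filter order is fixed (the audit trail depends on it): significance
filter, clumping, confounder blacklist, weak-instrument F filter, then
harmonization against the outcome.  Outputs are written to the configured
directory as TSV plus a JSON run manifest; machine-readable files carry
full precision, display formatting is applied separately.  Given the same
config and seed, outputs are byte-identical across runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .estimators import IVW_MRE, MREstimate, all_estimates
from .gwas_io import read_summary_stats, write_harmonized
from .harmonize import HarmonizedDataset, harmonize
from .instruments import (
    ClumpConfig,
    clump,
    exclude_snps,
    filter_by_f,
    filter_by_pvalue,
    read_blacklist,
    read_ld_matrix,
)
from .sensitivity import SensitivityReport, bh_adjust, sensitivity_report

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage name and reason."""


@dataclass
class PipelineConfig:
    exposure_path: str = ""
    outcome_path: str = ""
    exposure_columns: Mapping[str, str] | None = None
    outcome_columns: Mapping[str, str] | None = None
    exposure_name: str = ""
    outcome_name: str = ""
    p_threshold: float = 5.0e-8
    window_kb: float = 5000.0
    r2_threshold: float = 0.001
    ld_path: str | None = None
    blacklist_path: str | None = None
    min_f: float = 10.0
    maf_ambiguity: float = 0.08
    ivw_model: str = IVW_MRE
    n_boot: int = 1000
    phi: float = 1.0
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "mr_output"


@dataclass
class RunReport:
    estimates: list[MREstimate]
    sensitivity: SensitivityReport
    harmonized: HarmonizedDataset
    audit: dict
    config: PipelineConfig
    version: str = __version__


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"{name}: {exc}") from exc
        return wrapped
    return deco


def run_mr(config: PipelineConfig) -> RunReport:
    """Execute the full workflow and write all reports.

    Raises :class:`PipelineError` with the failing stage's name; fewer
    than 3 surviving harmonized pairs aborts with "insufficient
    instruments".
    """
    cfg = config
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    audit: dict = {"seed": cfg.seed}

    exposure = _stage("read exposure")(read_summary_stats)(
        cfg.exposure_path, cfg.exposure_columns, role="exposure",
        trait_name=cfg.exposure_name or None,
    )
    outcome = _stage("read outcome")(read_summary_stats)(
        cfg.outcome_path, cfg.outcome_columns, role="outcome",
        trait_name=cfg.outcome_name or None,
    )
    audit["exposure_input"] = len(exposure)
    audit["exposure_rows_dropped_on_read"] = dict(exposure.drop_counts)
    audit["outcome_input"] = len(outcome)

    sig = _stage("significance filter")(filter_by_pvalue)(exposure, cfg.p_threshold)
    audit["after_significance_filter"] = len(sig)
    log.info("significance filter: %d -> %d", len(exposure), len(sig))

    ld = read_ld_matrix(cfg.ld_path) if cfg.ld_path else None
    ccfg = ClumpConfig(
        p_threshold=cfg.p_threshold, window_kb=cfg.window_kb,
        r2_threshold=cfg.r2_threshold, ld=ld,
    )
    clumped = _stage("clumping")(clump)(sig, ccfg)
    audit["after_clumping"] = len(clumped)
    log.info("clumping: %d -> %d", len(sig), len(clumped))

    blacklist = read_blacklist(cfg.blacklist_path) if cfg.blacklist_path else {}
    excluded = _stage("confounder exclusion")(exclude_snps)(
        clumped, blacklist, reason="confounder-associated"
    )
    audit["after_blacklist"] = len(excluded)
    log.info("blacklist: %d -> %d", len(clumped), len(excluded))

    instr = _stage("F filter")(filter_by_f)(excluded, cfg.min_f)
    audit["after_f_filter"] = len(instr)
    audit["mean_f"] = instr.mean_f
    log.info("F filter: %d -> %d (mean F %.1f)", len(excluded), len(instr), instr.mean_f)

    data = _stage("harmonization")(harmonize)(instr, outcome, cfg.maf_ambiguity)
    audit["harmonized_pairs"] = len(data)
    audit["harmonization_audit"] = dict(data.audit)
    log.info("harmonization: %d -> %d", len(instr), len(data))
    if len(data) < 3:
        raise PipelineError("harmonization: insufficient instruments "
                            f"({len(data)} surviving pairs; need >= 3)")

    estimates = _stage("estimation")(all_estimates)(
        data, ivw_model=cfg.ivw_model, n_boot=cfg.n_boot, phi=cfg.phi, seed=cfg.seed
    )
    sens = _stage("sensitivity")(sensitivity_report)(
        data, alpha=cfg.alpha, ivw_model=cfg.ivw_model
    )
    raw_p = [e.pvalue for e in estimates]
    adjusted = _stage("BH adjustment")(bh_adjust)(
        [p for p in raw_p if np.isfinite(p)]
    )
    it = iter(adjusted)
    sens.adjusted_pvalues = tuple(
        float(next(it)) if np.isfinite(p) else float("nan") for p in raw_p
    )

    report = RunReport(estimates=estimates, sensitivity=sens, harmonized=data,
                       audit=audit, config=cfg)
    _stage("write outputs")(_write_outputs)(report, out_dir)
    return report


def _estimates_frame(report: RunReport) -> pd.DataFrame:
    rows = []
    for est, adj in zip(report.estimates, report.sensitivity.adjusted_pvalues):
        rows.append({
            "exposure": report.harmonized.exposure_name,
            "outcome": report.harmonized.outcome_name,
            "n_snp": est.n_snp,
            "method": est.method,
            "beta": est.beta,
            "se": est.se,
            "ci_low": est.ci_low,
            "ci_high": est.ci_high,
            "pvalue": est.pvalue,
            "pvalue_bh": adj,
        })
    return pd.DataFrame(rows)


def _write_outputs(report: RunReport, out_dir: Path) -> None:
    _estimates_frame(report).to_csv(out_dir / "estimates.tsv", sep="\t",
                                    index=False, na_rep="NA")
    write_harmonized(report.harmonized, out_dir / "harmonized.tsv")

    s = report.sensitivity
    sens_row = {
        "Q": s.heterogeneity.Q, "df": s.heterogeneity.df,
        "Q_pvalue": s.heterogeneity.pvalue, "I2_percent": s.heterogeneity.i2,
        "egger_intercept": s.pleiotropy.intercept,
        "egger_intercept_se": s.pleiotropy.se,
        "egger_intercept_pvalue": s.pleiotropy.pvalue,
        "heterogeneity_flag": s.heterogeneity_flag,
        "loo_unstable": s.loo.unstable,
        "recommended_method": s.recommended_method,
    }
    pd.DataFrame([sens_row]).to_csv(out_dir / "sensitivity.tsv", sep="\t", index=False)

    loo_rows = [
        {"excluded_snp": e.excluded, "beta": e.beta, "se": e.se,
         "ci_low": e.ci_low, "ci_high": e.ci_high}
        for e in s.loo.entries
    ]
    pd.DataFrame(loo_rows).to_csv(out_dir / "leave_one_out.tsv", sep="\t", index=False)

    manifest = {
        "version": report.version,
        "seed": report.config.seed,
        "config": {k: (dict(v) if isinstance(v, Mapping) else v)
                   for k, v in asdict(report.config).items()},
        "audit": report.audit,
        "sensitivity": sens_row,
        "outputs": ["estimates.tsv", "harmonized.tsv", "sensitivity.tsv",
                    "leave_one_out.tsv"],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))


def format_pvalue(p: float) -> str:
    """Display form: 3 decimals, scientific (m × 10^e) below 10^-3."""
    if not np.isfinite(p):
        return "NA"
    if p <= 0:
        return "0"
    if p >= 1e-3:
        return f"{p:.3f}"
    exponent = int(np.floor(np.log10(p)))
    mantissa = p / 10.0**exponent
    if round(mantissa, 2) >= 10:  # e.g. 9.996e-4 -> 1.00 x 10^-3
        mantissa, exponent = mantissa / 10.0, exponent + 1
    return f"{mantissa:.2f} × 10^{exponent}"


def format_estimates_table(report: RunReport) -> list[dict[str, str]]:
    """Display rows: beta/se/CI to 3 decimals, p in scientific below 1e-3."""
    rows = []
    for est in report.estimates:
        rows.append({
            "Exposure": report.harmonized.exposure_name,
            "Outcome": report.harmonized.outcome_name,
            "SNP": str(est.n_snp),
            "Method": est.method,
            "beta": f"{est.beta + 0.0:.3f}",
            "95%CI": f"{est.ci_low + 0.0:.3f}, {est.ci_high + 0.0:.3f}"
                     if np.isfinite(est.ci_low) else "NA",
            "Se": f"{est.se:.3f}" if np.isfinite(est.se) else "NA",
            "p-value": format_pvalue(est.pvalue),
        })
    return rows


def render_table(rows: list[dict[str, str]]) -> str:
    """Plain-text rendering of display rows (used by the CLI)."""
    if not rows:
        return ""
    cols = list(rows[0])
    widths = {c: max(len(c), *(len(r[c]) for r in rows)) for c in cols}
    lines = ["  ".join(c.ljust(widths[c]) for c in cols)]
    for r in rows:
        lines.append("  ".join(r[c].ljust(widths[c]) for c in cols))
    return "\n".join(lines)
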