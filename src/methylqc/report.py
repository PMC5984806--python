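"""End-to-end QC runs combining every check into one report.

``run_qc`` chains dye-bias correction, control metrics, detection
p-values, SNP genotyping (outlier log-odds and fingerprint conflicts), and
the sex check over one dataset, producing a per-sample table plus a
machine-readable summary. The expensive MCMC contamination fit is opt-in.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import __version__
from .contamination import ContaminationFit, fit_contamination, write_contamination_report
from .controls import control_metrics, flag_samples, load_policy, write_metric_report
from .exceptions import MethylQcError
from .genotyping import (
    AgreementResult,
    call_genotypes,
    check_snp_agreement,
    fit_snp_mixture,
    snp_outliers,
    write_agreement_report,
)
from .io import MethylationDataset
from .preprocess import compute_beta, correct_dye_bias, detection_pvalues, undetected_fraction
from .sex import check_sex, write_sex_report

SNP_OUTLIER_CUTOFF = -4.0  # average log2 odds above which a sample is suspect
DETECTION_FRACTION_CUTOFF = 0.01  # > 1% undetected probes fails the sample


@dataclass
class QcReport:
    """One row per sample with every per-sample QC outcome plus run metadata."""

    table: pd.DataFrame
    metric_results: pd.DataFrame
    agreement: Optional[AgreementResult]
    sex_result: Optional[object]
    contamination: Optional[ContaminationFit]
    summary: Dict = field(default_factory=dict)

    @property
    def any_failure(self) -> bool:
        return bool(self.summary.get("n_samples_failing_any_check", 0) > 0)


def run_qc(
    dataset: MethylationDataset,
    policy_path: Optional[Path | str] = None,
    conflict_threshold: float = 0.90,
    snp_outlier_cutoff: float = SNP_OUTLIER_CUTOFF,
    dye_correct: bool = True,
    contamination: bool = False,
    mcmc_iter: int = 10_000,
    mcmc_burn_in: int = 5_000,
    seed: int = 0,
) -> QcReport:
    """Run every applicable QC check on one dataset."""
    policy = load_policy(policy_path)
    if dye_correct:
        dataset = correct_dye_bias(dataset)

    samples = dataset.sample_ids
    out = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    out["donor_id"] = dataset.samples["donor_id"].reindex(samples)
    summary: Dict = {
        "methylqc_version": __version__,
        "seed": seed,
        "n_samples": int(len(samples)),
        "thresholds": {
            "control_metric_policy": {m.name: m.threshold for m in policy},
            "conflict_threshold": conflict_threshold,
            "snp_outlier_cutoff": snp_outlier_cutoff,
            "detection_p_alpha": 0.01,
            "detection_fraction_cutoff": DETECTION_FRACTION_CUTOFF,
        },
    }

    # control metrics
    metric_results = control_metrics(dataset, policy)
    metric_flags = flag_samples(metric_results, policy).reindex(samples).fillna(False)
    out["control_metrics_flagged"] = metric_flags.to_numpy()
    summary["n_flagged_by_control_metrics"] = int(metric_flags.sum())

    # detection p-values
    try:
        frac = undetected_fraction(detection_pvalues(dataset)).reindex(samples)
        out["undetected_fraction"] = frac.to_numpy()
        out["detection_flagged"] = (frac > DETECTION_FRACTION_CUTOFF).to_numpy()
        summary["n_flagged_by_detection_p"] = int(out["detection_flagged"].sum())
    except MethylQcError:
        out["undetected_fraction"] = np.nan
        out["detection_flagged"] = False
        summary["n_flagged_by_detection_p"] = None

    # genotyping: outliers + fingerprint conflicts
    beta = compute_beta(dataset)
    manifest = dataset.manifest
    agreement = None
    contamination_fit = None
    snp_ids = manifest.snp_probes().intersection(beta.beta.index) if manifest else []
    out["snp_outlier_logodds"] = np.nan
    out["snp_outlier_flagged"] = False
    out["n_conflicts"] = 0
    if len(snp_ids) >= 5 and len(samples) >= 2:
        beta_snp = beta.restrict(snp_ids)
        model = fit_snp_mixture(beta_snp, seed=seed)
        posts = call_genotypes(model, beta_snp)
        o_n = snp_outliers(posts).reindex(samples)
        out["snp_outlier_logodds"] = o_n.to_numpy()
        out["snp_outlier_flagged"] = (o_n > snp_outlier_cutoff).to_numpy()
        agreement = check_snp_agreement(posts, dataset.samples["donor_id"],
                                        conflict_threshold)
        conflict_counts = pd.concat([
            agreement.conflicts["sample_a"], agreement.conflicts["sample_b"],
        ]).value_counts()
        out["n_conflicts"] = conflict_counts.reindex(samples).fillna(0).astype(int).to_numpy()
        summary["n_pairwise_comparisons"] = int(len(agreement.pairs))
        summary["n_conflicts"] = int(len(agreement.conflicts))
        summary["n_flagged_by_snp_outliers"] = int(out["snp_outlier_flagged"].sum())
        if contamination:
            contamination_fit = fit_contamination(
                beta_snp, init=posts, n_iter=mcmc_iter,
                burn_in=mcmc_burn_in, seed=seed)
            out["gamma_hat"] = contamination_fit.gamma.reindex(samples).to_numpy()

    # sex check
    sex_result = None
    out["sex_status"] = "not_run"
    recorded = dataset.samples["recorded_sex"].reindex(samples)
    if (recorded == "male").any() and (recorded == "female").any():
        sex_result = check_sex(dataset)
        st = sex_result.table.reindex(samples)
        out["tX_norm"] = st["tX_norm"].to_numpy()
        out["tY_norm"] = st["tY_norm"].to_numpy()
        out["predicted_sex"] = st["predicted_sex"].to_numpy()
        out["sex_status"] = st["status"].to_numpy()
        summary["n_sex_mismatches"] = int((st["status"] == "mismatch").sum())
        summary["n_sex_unclear"] = int((st["status"] == "unclear").sum())

    failing = (
        out["control_metrics_flagged"].astype(bool)
        | out["detection_flagged"].astype(bool)
        | out["snp_outlier_flagged"].astype(bool)
        | (out["n_conflicts"] > 0)
        | (out["sex_status"] == "mismatch")
    )
    out["fails_any_check"] = failing.to_numpy()
    summary["n_samples_failing_any_check"] = int(failing.sum())
    summary["config_hash"] = hashlib.sha256(
        json.dumps(summary["thresholds"], sort_keys=True).encode()).hexdigest()[:16]

    return QcReport(table=out, metric_results=metric_results, agreement=agreement,
                    sex_result=sex_result, contamination=contamination_fit,
                    summary=summary)


def write_report(report: QcReport, out_dir: Path | str) -> None:
    """Write qc_report.tsv, conflicts.tsv, sex_report.tsv, contamination.tsv, summary.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report.table.reset_index().to_csv(out_dir / "qc_report.tsv", sep="\t",
                                      index=False, na_rep="")
    write_metric_report(report.metric_results, out_dir / "control_metrics.tsv")
    if report.agreement is not None:
        write_agreement_report(report.agreement, out_dir / "conflicts.tsv")
    if report.sex_result is not None:
        write_sex_report(report.sex_result, out_dir / "sex_report.tsv")
    if report.contamination is not None:
        write_contamination_report(report.contamination, out_dir / "contamination.tsv")
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(report.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
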