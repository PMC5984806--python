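"""BeadArray control metrics.

Seventeen per-sample metrics computed from the dedicated control probes
monitor the experimental steps of the Infinium assay (staining, extension,
hybridization, target removal, bisulfite conversion, specificity,
non-polymorphic performance, restoration). Each metric is a dimensionless
signal-to-background ratio; a sample is flagged when any metric falls
strictly below its threshold, so a value exactly at threshold passes.
Metrics whose probe groups are absent report as missing ("n.a.") and never
flag a sample.

The probe groupings and thresholds are configuration data (see
``data/control_policy.yaml``), editable to match any manifest's control
probe naming.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError
from .io import MethylationDataset

METRIC_NAMES = [
    "Restoration",
    "Staining green",
    "Staining red",
    "Extension green",
    "Extension red",
    "Hybridization high/medium",
    "Hybridization medium/low",
    "Target removal 1",
    "Target removal 2",
    "Bisulfite conversion I green",
    "Bisulfite conversion I red",
    "Bisulfite conversion II",
    "Specificity I green",
    "Specificity I red",
    "Specificity II",
    "Non-polymorphic green",
    "Non-polymorphic red",
]


@dataclass(frozen=True)
class GroupSpec:
    pattern: str
    channel: str  # "grn" or "red"


@dataclass(frozen=True)
class MetricSpec:
    name: str
    numerator: GroupSpec
    denominator: GroupSpec
    threshold: float


def load_policy(path: Optional[Path | str] = None) -> List[MetricSpec]:
    """Load a metric policy from YAML; with no path, the shipped default."""
    if path is None:
        text = resources.files("methylqc").joinpath("data/control_policy.yaml").read_text()
    else:
        text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
        metrics = []
        for entry in raw["metrics"]:
            metrics.append(MetricSpec(
                name=entry["name"],
                numerator=GroupSpec(**entry["numerator"]),
                denominator=GroupSpec(**entry["denominator"]),
                threshold=float(entry["threshold"]),
            ))
    except (KeyError, TypeError, yaml.YAMLError) as exc:
        raise ConfigurationError(f"malformed control policy: {exc}") from exc
    for m in metrics:
        for g in (m.numerator, m.denominator):
            if g.channel not in ("grn", "red"):
                raise ConfigurationError(
                    f"metric '{m.name}': channel must be grn or red, got '{g.channel}'")
    return metrics


def _group_mean(dataset: MethylationDataset, group: GroupSpec) -> np.ndarray:
    frame = dataset.controls_grn if group.channel == "grn" else dataset.controls_red
    rx = re.compile(group.pattern)
    mask = frame.index.map(lambda p: bool(rx.search(str(p))))
    sub = frame.loc[np.asarray(mask, dtype=bool)].to_numpy(dtype=float)
    if sub.shape[0] == 0:
        return np.full(frame.shape[1], np.nan)
    with np.errstate(invalid="ignore"):
        out = np.nanmean(sub, axis=0)
    return out


def control_metrics(
    dataset: MethylationDataset,
    policy: Optional[Sequence[MetricSpec]] = None,
) -> pd.DataFrame:
    """Compute every policy metric per sample.

    Returns a tidy frame with one row per sample x metric and columns
    ``sample_id, metric, value, threshold, flagged`` where ``flagged`` is a
    nullable boolean (pd.NA for n.a. metrics).
    """
    if policy is None:
        policy = load_policy()
    rows = []
    samples = dataset.sample_ids
    for spec in policy:
        num = _group_mean(dataset, spec.numerator)
        den = _group_mean(dataset, spec.denominator)
        with np.errstate(invalid="ignore", divide="ignore"):
            value = np.where(den > 0, num / den, np.nan)
        for s, v in zip(samples, value):
            flagged = bool(v < spec.threshold) if np.isfinite(v) else pd.NA
            rows.append((s, spec.name, v if np.isfinite(v) else np.nan,
                         spec.threshold, flagged))
    out = pd.DataFrame(rows, columns=["sample_id", "metric", "value", "threshold", "flagged"])
    out["flagged"] = out["flagged"].astype("boolean")
    return out


def flag_samples(
    results: pd.DataFrame,
    policy: Optional[Sequence[MetricSpec]] = None,
) -> pd.Series:
    """Per-sample "flagged by any metric" indicator.

    A sample is flagged iff any of its metrics falls strictly below its
    threshold; n.a. metrics never flag. Raises
    :class:`ConfigurationError` when the policy names a metric absent from
    the results.
    """
    if policy is None:
        policy = load_policy()
    have = set(results["metric"])
    unknown = [m.name for m in policy if m.name not in have]
    if unknown:
        raise ConfigurationError(f"policy names unknown metrics: {unknown}")
    thresholds = {m.name: m.threshold for m in policy}
    sub = results[results["metric"].isin(thresholds)]
    below = sub["value"] < sub["metric"].map(thresholds)
    below = below.fillna(False) & sub["value"].notna()
    return below.groupby(sub["sample_id"]).any().rename("flagged")


def write_metric_report(results: pd.DataFrame, path: Path | str) -> None:
    """Export the per-sample x metric report as TSV (missing as empty)."""
    results.to_csv(path, sep="\t", index=False, na_rep="")
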