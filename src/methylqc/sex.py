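"""Sex inference from normalized allosomal intensities.

Total intensity T = U + M tracks copy number, so probes on the X and Y
chromosomes separate male (XY) from female (XX) samples. Each sample is
summarised by the mean total intensity over X probes and over Y probes,
both normalized by the mean over autosomal probes to cancel differences in
post-amplification DNA concentration.

Cutoffs between the sexes are learned from the recorded (possibly partly
wrong) labels with the Hodges-Lehmann estimator — the median of all
pairwise male/female averages — which tolerates a substantial fraction of
mislabeled samples. A sample is called male when it falls below the X
cutoff and above the Y cutoff, female in the opposite quadrant, and
"unclear" in the remaining two quadrants (the upper-right region is where
an XXY karyotype such as Klinefelter syndrome would land). Ties exactly on
a cutoff are conservatively unclear.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import Manifest, MethylationDataset


@dataclass
class SexCheckResult:
    """Per-sample normalized intensities, learned cutoffs, and calls."""

    table: pd.DataFrame  # tX_norm, tY_norm, predicted_sex, recorded_sex, mismatch, status
    cutoff_x: float
    cutoff_y: float


def normalized_chr_intensities(
    dataset: MethylationDataset,
    manifest: Optional[Manifest] = None,
) -> pd.DataFrame:
    """Mean total intensity over X and Y probes, each normalized by the autosomal mean."""
    manifest = manifest or dataset.manifest
    if manifest is None:
        raise ValidationError("sex check requires a manifest")
    total = dataset.total_intensity()
    auto = total.reindex(manifest.autosomal_probes().intersection(total.index))
    x = total.reindex(manifest.x_probes().intersection(total.index))
    y = total.reindex(manifest.y_probes().intersection(total.index))
    if auto.empty or x.empty or y.empty:
        raise ValidationError("manifest must label autosomal, X and Y probes present in data")
    auto_mean = np.nanmean(auto.to_numpy(dtype=float), axis=0)
    if not (auto_mean > 0).all():
        raise ValidationError("autosomal mean intensity is zero for some sample")
    tx = np.nanmean(x.to_numpy(dtype=float), axis=0) / auto_mean
    ty = np.nanmean(y.to_numpy(dtype=float), axis=0) / auto_mean
    return pd.DataFrame({"tX_norm": tx, "tY_norm": ty}, index=dataset.sample_ids)


def hodges_lehmann_cutoff(values: pd.Series, recorded_sex: pd.Series) -> float:
    """Median of all pairwise (male, female) averages of ``values``.

    Robust to a minority of wrong labels; raises when either sex class is
    empty, in which case cutoffs must be supplied manually.
    """
    sex = recorded_sex.reindex(values.index)
    males = values[sex == "male"].dropna().to_numpy(dtype=float)
    females = values[sex == "female"].dropna().to_numpy(dtype=float)
    if males.size == 0 or females.size == 0:
        raise ValidationError(
            "need at least one recorded male and one female to learn a cutoff; "
            "supply cutoffs manually otherwise")
    pair_means = (males[:, None] + females[None, :]) / 2.0
    return float(np.median(pair_means))


def predict_sex(
    tx_norm: pd.Series,
    ty_norm: pd.Series,
    cutoff_x: float,
    cutoff_y: float,
    recorded_sex: Optional[pd.Series] = None,
) -> SexCheckResult:
    """Quadrant-based call: male = (low X, high Y); female = (high X, low Y).

    Samples in the lower-left or upper-right quadrant — where the X- and
    Y-based calls disagree — are "unclear" and never counted as mismatches.
    """
    idx = tx_norm.index
    tx = tx_norm.to_numpy(dtype=float)
    ty = ty_norm.reindex(idx).to_numpy(dtype=float)
    male = (tx < cutoff_x) & (ty > cutoff_y)
    female = (tx > cutoff_x) & (ty < cutoff_y)
    predicted = np.where(male, "male", np.where(female, "female", "unclear"))

    if recorded_sex is None:
        recorded = np.full(len(idx), "unknown", dtype=object)
    else:
        recorded = recorded_sex.reindex(idx).fillna("unknown").to_numpy(dtype=object)
    mismatch = (predicted != "unclear") & (recorded != "unknown") & (predicted != recorded)
    status = np.where(predicted == "unclear", "unclear",
                      np.where(mismatch, "mismatch", "ok"))
    table = pd.DataFrame({
        "tX_norm": tx, "tY_norm": ty,
        "predicted_sex": predicted, "recorded_sex": recorded,
        "mismatch": mismatch, "status": status,
    }, index=idx)
    return SexCheckResult(table=table, cutoff_x=cutoff_x, cutoff_y=cutoff_y)


def check_sex(
    dataset: MethylationDataset,
    manifest: Optional[Manifest] = None,
    cutoffs: Optional[Tuple[float, float]] = None,
) -> SexCheckResult:
    """Full pipeline: normalized intensities, learned cutoffs, quadrant calls."""
    norm = normalized_chr_intensities(dataset, manifest)
    recorded = dataset.samples["recorded_sex"]
    if cutoffs is None:
        cutoffs = (
            hodges_lehmann_cutoff(norm["tX_norm"], recorded),
            hodges_lehmann_cutoff(norm["tY_norm"], recorded),
        )
    return predict_sex(norm["tX_norm"], norm["tY_norm"], cutoffs[0], cutoffs[1], recorded)


def write_sex_report(result: SexCheckResult, path) -> None:
    out = result.table.reset_index(names="sample_id")
    cols = ["sample_id", "tX_norm", "tY_norm", "predicted_sex", "recorded_sex", "status"]
    out[cols].to_csv(path, sep="\t", index=False, na_rep="")
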