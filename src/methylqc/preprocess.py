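"""Methylation quantification and signal-level preprocessing.

The methylation level at a locus is summarised by the beta-value
``beta = M / (M + U)``, the proportion of methylated signal. No offset
constant is added; a zero denominator yields a missing value rather than 0.

Dye bias — the systematic intensity difference between the green and red
channels of the two-color assay — is corrected with a RELIC-style log-log
regression on internal control probes measured in both channels (the
staining and extension categories), rescaling the red channel per sample.

Detection p-values quantify the probability that a probe's total intensity
U + M arises from background, under a normal model estimated from the
negative-control probes of the matching channel(s).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .io import Manifest, MethylationDataset

DYE_BIAS_CONTROL_CATEGORIES = ("staining", "extension")


@dataclass
class BetaMatrix:
    """Probe x sample matrix of beta-values in [0, 1], NaN where undefined."""

    beta: pd.DataFrame
    source: Optional[MethylationDataset] = None

    def __post_init__(self) -> None:
        vals = self.beta.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValidationError("beta-values must lie in [0, 1]")

    def restrict(self, probe_ids) -> "BetaMatrix":
        return BetaMatrix(self.beta.loc[probe_ids], source=self.source)


def compute_beta(dataset: MethylationDataset) -> BetaMatrix:
    """beta[i, n] = M / (M + U); missing where the denominator is zero."""
    U = dataset.U.to_numpy(dtype=float)
    M = dataset.M.to_numpy(dtype=float)
    total = U + M
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(total > 0, M / total, np.nan)
    return BetaMatrix(
        pd.DataFrame(beta, index=dataset.U.index, columns=dataset.U.columns),
        source=dataset,
    )


def _red_probe_mask(manifest: Manifest, probes: pd.Index) -> tuple[np.ndarray, np.ndarray]:
    """Masks of probes whose U (resp. M) intensity is measured in red."""
    design = manifest.table.reindex(probes)["channel_design"].to_numpy()
    u_red = (design == "typeI_red") | (design == "typeII")
    m_red = design == "typeI_red"
    return u_red, m_red


def dye_bias_pairs(dataset: MethylationDataset) -> list[tuple[str, str]]:
    """Matched (green-probe, red-probe) internal control pairs.

    Control probes of the staining and extension categories are assigned to
    a channel side by their dominant channel (mean across samples at least
    twice the other channel); each side is sorted by its own-channel mean
    and paired rank-wise, emulating duplicate control designs that measure
    the same target once per channel. Probes with comparable channels
    (backgrounds) are dropped.
    """
    if dataset.manifest is None:
        raise ValidationError("dye-bias correction requires a manifest")
    manifest = dataset.manifest
    probes = manifest.control_probes().intersection(dataset.controls_grn.index)
    cats = manifest.table.loc[probes, "control_category"]
    probes = probes[cats.isin(DYE_BIAS_CONTROL_CATEGORIES)]
    mg = np.nanmean(dataset.controls_grn.loc[probes].to_numpy(dtype=float), axis=1)
    mr = np.nanmean(dataset.controls_red.loc[probes].to_numpy(dtype=float), axis=1)
    green_side = [(m, p) for p, m, r in zip(probes, mg, mr)
                  if np.isfinite(m) and np.isfinite(r) and m > 2 * r]
    red_side = [(m, p) for p, g, m in zip(probes, mg, mr)
                if np.isfinite(g) and np.isfinite(m) and m > 2 * g]
    green_side.sort(key=lambda t: (-t[0], t[1]))
    red_side.sort(key=lambda t: (-t[0], t[1]))
    return [(g[1], r[1]) for g, r in zip(green_side, red_side)]


def correct_dye_bias(dataset: MethylationDataset, min_pairs: int = 3) -> MethylationDataset:
    """Rescale the red channel per sample via control-pair regression.

    Matched green/red internal control pairs (see :func:`dye_bias_pairs`)
    provide per-sample (red, green) intensity pairs of equal expected
    signal; a linear regression of log green on log red defines the
    monotone map ``red -> exp(a) * red**b`` applied to every red-channel
    intensity of the sample. The green channel is untouched. Samples with
    fewer than ``min_pairs`` usable pairs are skipped and flagged in
    ``samples["dye_bias_skipped"]``.
    """
    manifest = dataset.manifest
    pairs = dye_bias_pairs(dataset)
    green_probes = [p for p, _ in pairs]
    red_probes = [p for _, p in pairs]

    U = dataset.U.to_numpy(dtype=float).copy()
    M = dataset.M.to_numpy(dtype=float).copy()
    c_red = dataset.controls_red.to_numpy(dtype=float).copy()
    u_red, m_red = _red_probe_mask(manifest, dataset.U.index)

    skipped = []
    for s, sample in enumerate(dataset.sample_ids):
        if len(pairs) < min_pairs:
            skipped.append(sample)
            continue
        g = dataset.controls_grn.loc[green_probes, sample].to_numpy(dtype=float)
        r = dataset.controls_red.loc[red_probes, sample].to_numpy(dtype=float)
        ok = np.isfinite(g) & np.isfinite(r) & (g > 0) & (r > 0)
        if ok.sum() < min_pairs:
            skipped.append(sample)
            continue
        x, y = np.log(r[ok]), np.log(g[ok])
        # slope shrunk toward 1 (lambda in squared log units) so that a
        # handful of noisy pairs cannot produce a wildly nonlinear map;
        # with many pairs the data dominate
        lam = 1.0
        xm, ym = x.mean(), y.mean()
        b = (np.dot(x - xm, y - ym) + lam) / (np.dot(x - xm, x - xm) + lam)
        a = ym - b * xm
        scale = np.exp(a)

        def fix(x: np.ndarray) -> np.ndarray:
            with np.errstate(invalid="ignore"):
                return np.where(x > 0, scale * np.power(x, b), x)

        U[u_red, s] = fix(U[u_red, s])
        M[m_red, s] = fix(M[m_red, s])
        c_red[:, s] = fix(c_red[:, s])

    samples = dataset.samples.copy()
    samples["dye_bias_skipped"] = samples.index.isin(skipped)
    return MethylationDataset(
        U=pd.DataFrame(U, index=dataset.U.index, columns=dataset.U.columns),
        M=pd.DataFrame(M, index=dataset.M.index, columns=dataset.M.columns),
        controls_grn=dataset.controls_grn.copy(),
        controls_red=pd.DataFrame(c_red, index=dataset.controls_red.index,
                                  columns=dataset.controls_red.columns),
        samples=samples,
        manifest=manifest,
    )


def detection_pvalues(dataset: MethylationDataset) -> pd.DataFrame:
    """Upper-tail p-values of total intensity against negative-control background.

    Backgrounds are channel-matched: type I probes (both signals in one
    channel) are compared against twice the negative-control mean of that
    channel with variance doubled; type II probes (one signal per channel)
    against the sum of the two channel backgrounds.
    """
    if dataset.manifest is None:
        raise ValidationError("detection p-values require a manifest")
    neg = dataset.manifest.control_probes("negative").intersection(dataset.controls_grn.index)
    if len(neg) == 0:
        raise ValidationError("no negative-control probes available")

    neg_g = dataset.controls_grn.loc[neg].to_numpy(dtype=float)
    neg_r = dataset.controls_red.loc[neg].to_numpy(dtype=float)
    mu_g, sd_g = np.nanmean(neg_g, axis=0), np.nanstd(neg_g, axis=0, ddof=1)
    mu_r, sd_r = np.nanmean(neg_r, axis=0), np.nanstd(neg_r, axis=0, ddof=1)
    sd_g = np.where(sd_g > 0, sd_g, 1.0)
    sd_r = np.where(sd_r > 0, sd_r, 1.0)

    design = dataset.manifest.table.reindex(dataset.U.index)["channel_design"].to_numpy()
    total = dataset.total_intensity().to_numpy(dtype=float)

    mean = np.empty_like(total)
    sd = np.empty_like(total)
    for mask, m, s in (
        (design == "typeI_green", 2 * mu_g, np.sqrt(2) * sd_g),
        (design == "typeI_red", 2 * mu_r, np.sqrt(2) * sd_r),
        (design == "typeII", mu_g + mu_r, np.sqrt(sd_g ** 2 + sd_r ** 2)),
    ):
        mean[mask] = m
        sd[mask] = s

    with np.errstate(invalid="ignore"):
        p = stats.norm.sf(total, loc=mean, scale=sd)
    p = np.where(np.isfinite(total), p, np.nan)
    return pd.DataFrame(p, index=dataset.U.index, columns=dataset.U.columns)


def undetected_fraction(pvals: pd.DataFrame, alpha: float = 0.01) -> pd.Series:
    """Per-sample fraction of probes with detection p-value above ``alpha``."""
    arr = pvals.to_numpy(dtype=float)
    n_obs = np.isfinite(arr).sum(axis=0)
    n_fail = np.nansum(arr > alpha, axis=0)
    with np.errstate(invalid="ignore"):
        frac = np.where(n_obs > 0, n_fail / n_obs, np.nan)
    return pd.Series(frac, index=pvals.columns, name="undetected_fraction")
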