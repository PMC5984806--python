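"""Core dataset and manifest containers plus TSV readers/writers.

The interchange formats are plain tab-separated files:

* intensity TSV — header ``probe_id\tsample_id\tU\tM``, one row per
  (probe, sample); missing intensities are empty fields.
* controls TSV — header ``probe_id\tsample_id\tgrn\tred``.
* samples TSV — header ``sample_id\tdonor_id\trecorded_sex``.
* manifest TSV — header ``probe_id\tchromosome\tprobe_class\t``
  ``control_category\tchannel_design`` plus optional integer columns
  ``address_a``/``address_b`` used only by the IDAT reader.

All files are UTF-8, unquoted, with missing values encoded as empty fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

AUTOSOMES = {str(i) for i in range(1, 23)}
CHROMOSOMES = AUTOSOMES | {"X", "Y"}
PROBE_CLASSES = {"cpg", "snp", "control"}
CONTROL_CATEGORIES = {
    "staining",
    "extension",
    "hybridization",
    "target_removal",
    "bisulfite_conversion_I",
    "bisulfite_conversion_II",
    "specificity_I",
    "specificity_II",
    "non_polymorphic",
    "restoration",
    "negative",
}
CHANNEL_DESIGNS = {"typeI_green", "typeI_red", "typeII"}
SEXES = {"male", "female", "unknown"}

MANIFEST_COLUMNS = [
    "probe_id",
    "chromosome",
    "probe_class",
    "control_category",
    "channel_design",
]


@dataclass
class Manifest:
    """Per-probe annotation driving probe-subset selection.

    The table is indexed by ``probe_id`` and carries ``chromosome``
    (1..22, X, Y), ``probe_class`` (cpg / snp / control), an optional
    ``control_category`` (present iff the probe is a control) and
    ``channel_design`` (typeI_green / typeI_red / typeII).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        t = self.table
        if t.index.name != "probe_id":
            raise ValidationError("manifest table must be indexed by probe_id")
        if t.index.duplicated().any():
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe_id in manifest: {dups[:5]}")
        for col in ("chromosome", "probe_class", "channel_design"):
            if col not in t.columns:
                raise FormatError(f"manifest missing required column '{col}'")
        bad_chrom = set(t["chromosome"].astype(str)) - CHROMOSOMES
        if bad_chrom:
            raise ValidationError(f"unknown chromosome labels: {sorted(bad_chrom)[:5]}")
        bad_class = set(t["probe_class"]) - PROBE_CLASSES
        if bad_class:
            raise ValidationError(f"unknown probe_class values: {sorted(bad_class)}")
        bad_design = set(t["channel_design"]) - CHANNEL_DESIGNS
        if bad_design:
            raise ValidationError(f"unknown channel_design values: {sorted(bad_design)}")
        is_control = t["probe_class"] == "control"
        if "control_category" not in t.columns:
            if is_control.any():
                raise FormatError("manifest missing required column 'control_category'")
        else:
            cat = t["control_category"]
            if (is_control & cat.isna()).any():
                raise ValidationError("control probes must carry a control_category")
            if (~is_control & cat.notna()).any():
                raise ValidationError("control_category present on non-control probes")
            bad_cat = set(cat.dropna()) - CONTROL_CATEGORIES
            if bad_cat:
                raise ValidationError(f"unknown control_category values: {sorted(bad_cat)}")
        snp_ids = t.index[t["probe_class"] == "snp"]
        bad_snp = [p for p in snp_ids if not str(p).startswith("rs")]
        if bad_snp:
            raise ValidationError(
                f"snp-class probe identifiers must start with 'rs': {bad_snp[:5]}"
            )

    # -- probe subset selectors; together these partition the manifest ------

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def autosomal_probes(self) -> pd.Index:
        t = self.table
        mask = (t["probe_class"] == "cpg") & t["chromosome"].astype(str).isin(AUTOSOMES)
        return t.index[mask]

    def x_probes(self) -> pd.Index:
        t = self.table
        return t.index[(t["probe_class"] == "cpg") & (t["chromosome"].astype(str) == "X")]

    def y_probes(self) -> pd.Index:
        t = self.table
        return t.index[(t["probe_class"] == "cpg") & (t["chromosome"].astype(str) == "Y")]

    def snp_probes(self) -> pd.Index:
        return self.table.index[self.table["probe_class"] == "snp"]

    def control_probes(self, category: Optional[str] = None) -> pd.Index:
        t = self.table
        mask = t["probe_class"] == "control"
        if category is not None:
            if category not in CONTROL_CATEGORIES:
                raise ValidationError(f"unknown control category '{category}'")
            mask &= t["control_category"] == category
        return t.index[mask]

    def channel_design_of(self, probe_ids: Iterable[str]) -> pd.Series:
        return self.table.loc[list(probe_ids), "channel_design"]


@dataclass
class MethylationDataset:
    """Paired unmethylated/methylated intensity matrices plus controls.

    ``U`` and ``M`` are probe x sample DataFrames sharing index and columns;
    ``controls_grn``/``controls_red`` hold control-probe intensities per color
    channel; ``samples`` is indexed by sample_id with ``donor_id`` and
    ``recorded_sex`` columns. Intensities are non-negative floats; missing
    values are NaN (never silently zero), so downstream averages skip them.
    """

    U: pd.DataFrame
    M: pd.DataFrame
    controls_grn: pd.DataFrame
    controls_red: pd.DataFrame
    samples: pd.DataFrame
    manifest: Optional[Manifest] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.U.index.equals(self.M.index):
            raise ValidationError("U and M must share the same probe index")
        if not self.U.columns.equals(self.M.columns):
            raise ValidationError("U and M must share the same sample columns")
        if not self.controls_grn.index.equals(self.controls_red.index):
            raise ValidationError("control channels must share the same probe index")
        for name, df in (("U", self.U), ("M", self.M),
                         ("controls_grn", self.controls_grn),
                         ("controls_red", self.controls_red)):
            vals = df.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValidationError(f"negative intensities in {name}")
        missing_meta = set(self.U.columns) - set(self.samples.index)
        if missing_meta:
            raise ValidationError(f"samples table missing entries for {sorted(missing_meta)[:5]}")
        bad_sex = set(self.samples["recorded_sex"].dropna()) - SEXES
        if bad_sex:
            raise ValidationError(f"unknown recorded_sex values: {sorted(bad_sex)}")
        if self.manifest is not None:
            known = set(self.manifest.probe_ids)
            orphans = [p for p in self.U.index if p not in known]
            orphans += [p for p in self.controls_grn.index if p not in known]
            if orphans:
                raise ValidationError(
                    f"probes absent from manifest: {orphans[:5]}"
                    + ("..." if len(orphans) > 5 else "")
                )

    @property
    def sample_ids(self) -> pd.Index:
        return self.U.columns

    @property
    def n_samples(self) -> int:
        return self.U.shape[1]

    def total_intensity(self) -> pd.DataFrame:
        """Per-probe total intensity T = U + M (NaN where either is missing)."""
        return self.U + self.M


# ---------------------------------------------------------------------------
# TSV reading / writing


def _read_tsv(path: Path | str, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "sample_id": str},
                     na_values=[""], keep_default_na=True)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing required column '{col}'")
    return df


def read_manifest(path: Path | str) -> Manifest:
    """Read a manifest TSV into a validated :class:`Manifest`."""
    df = _read_tsv(path, ["probe_id", "chromosome", "probe_class", "channel_design"])
    if df["probe_id"].duplicated().any():
        raise ValidationError("duplicate probe_id in manifest file")
    df = df.set_index("probe_id")
    df["chromosome"] = df["chromosome"].astype(str)
    if "control_category" not in df.columns:
        df["control_category"] = pd.Series(pd.NA, index=df.index, dtype="object")
    for col in ("address_a", "address_b"):
        if col in df.columns:
            df[col] = df[col].astype("Int64")
    return Manifest(df)


def _pivot(df: pd.DataFrame, value: str) -> pd.DataFrame:
    wide = df.pivot(index="probe_id", columns="sample_id", values=value)
    wide.index.name = "probe_id"
    wide.columns.name = None
    return wide.astype(float)


def read_dataset(
    intensity_path: Path | str,
    manifest_path: Path | str,
    controls_path: Optional[Path | str] = None,
    samples_path: Optional[Path | str] = None,
) -> MethylationDataset:
    """Read intensity/controls/samples TSVs into a validated dataset.

    Probes present in the intensity file but absent from the manifest are
    rejected with a :class:`ValidationError`.
    """
    manifest = read_manifest(manifest_path)
    inten = _read_tsv(intensity_path, ["probe_id", "sample_id", "U", "M"])
    if inten.duplicated(["probe_id", "sample_id"]).any():
        raise ValidationError("duplicate (probe_id, sample_id) rows in intensity file")
    U = _pivot(inten, "U")
    M = _pivot(inten, "M")

    if controls_path is not None:
        ctl = _read_tsv(controls_path, ["probe_id", "sample_id", "grn", "red"])
        controls_grn = _pivot(ctl, "grn")
        controls_red = _pivot(ctl, "red")
        controls_grn = controls_grn.reindex(columns=U.columns)
        controls_red = controls_red.reindex(columns=U.columns)
    else:
        controls_grn = pd.DataFrame(index=pd.Index([], name="probe_id"), columns=U.columns, dtype=float)
        controls_red = controls_grn.copy()

    if samples_path is not None:
        samp = _read_tsv(samples_path, ["sample_id"])
        samp = samp.set_index("sample_id")
        if "donor_id" not in samp.columns:
            samp["donor_id"] = samp.index
        if "recorded_sex" not in samp.columns:
            samp["recorded_sex"] = "unknown"
        samp["recorded_sex"] = samp["recorded_sex"].fillna("unknown")
    else:
        samp = pd.DataFrame(
            {"donor_id": U.columns, "recorded_sex": "unknown"},
            index=pd.Index(U.columns, name="sample_id"),
        )

    return MethylationDataset(U=U, M=M, controls_grn=controls_grn,
                              controls_red=controls_red, samples=samp,
                              manifest=manifest)


def _melt(df: pd.DataFrame, value_names: Sequence[str],
          frames: Sequence[pd.DataFrame]) -> pd.DataFrame:
    long_frames = []
    for name, frame in zip(value_names, frames):
        m = frame.stack(future_stack=True).rename(name)
        long_frames.append(m)
    out = pd.concat(long_frames, axis=1).reset_index()
    out.columns = ["probe_id", "sample_id", *value_names]
    return out


def write_dataset(
    dataset: MethylationDataset,
    intensity_path: Path | str,
    controls_path: Optional[Path | str] = None,
    samples_path: Optional[Path | str] = None,
) -> None:
    """Write a dataset back to the TSV dialects read by :func:`read_dataset`."""
    inten = _melt(dataset.U, ["U", "M"], [dataset.U, dataset.M])
    inten.to_csv(intensity_path, sep="\t", index=False, na_rep="")
    if controls_path is not None:
        ctl = _melt(dataset.controls_grn, ["grn", "red"],
                    [dataset.controls_grn, dataset.controls_red])
        ctl.to_csv(controls_path, sep="\t", index=False, na_rep="")
    if samples_path is not None:
        dataset.samples.reset_index().to_csv(samples_path, sep="\t", index=False, na_rep="")


def write_manifest(manifest: Manifest, path: Path | str) -> None:
    manifest.table.reset_index().to_csv(path, sep="\t", index=False, na_rep="")
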