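"""Minimal reader (and test-support writer) for Illumina IDAT intensity files.

Only the fields needed for intensity extraction are handled: the probe count
(field 1000), the bead-address identifiers (field 102, "IlluminaID") and the
per-address mean intensities (field 104, "Mean"). Files must be format
version 3 or later. The address-to-probe mapping comes from the manifest's
``address_a``/``address_b`` columns, so no vendor manifest is bundled.
"""

from __future__ import annotations

import logging
import struct
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError
from .io import Manifest, MethylationDataset

logger = logging.getLogger(__name__)

_MAGIC = b"IDAT"
_FIELD_N_PROBES = 1000
_FIELD_ILLUMINA_ID = 102
_FIELD_MEAN = 104


def read_idat(path: Path | str) -> Dict[str, np.ndarray]:
    """Decode one IDAT file into ``{"ids": int32 array, "means": uint16 array}``."""
    path = Path(path)
    data = path.read_bytes()
    if len(data) < 16 or data[:4] != _MAGIC:
        raise FormatError(f"{path.name}: not an IDAT file (bad magic bytes)")
    version = struct.unpack_from("<q", data, 4)[0]
    if version < 3:
        raise FormatError(f"{path.name}: unsupported IDAT version {version}")
    try:
        n_fields = struct.unpack_from("<i", data, 12)[0]
        offsets = {}
        pos = 16
        for _ in range(n_fields):
            code, offset = struct.unpack_from("<Hq", data, pos)
            offsets[code] = offset
            pos += 10
        n = struct.unpack_from("<i", data, offsets[_FIELD_N_PROBES])[0]
        ids = np.frombuffer(data, dtype="<i4", count=n,
                            offset=offsets[_FIELD_ILLUMINA_ID])
        means = np.frombuffer(data, dtype="<u2", count=n,
                              offset=offsets[_FIELD_MEAN])
    except (struct.error, KeyError, ValueError) as exc:
        raise FormatError(f"{path.name}: truncated or malformed IDAT file ({exc})") from exc
    if n == 0:
        raise ValidationError(f"{path.name}: IDAT file contains zero probe records")
    return {"ids": ids.copy(), "means": means.astype(float)}


def write_idat(path: Path | str, ids: np.ndarray, means: np.ndarray) -> None:
    """Write a version-3 IDAT file carrying only ids and mean intensities."""
    ids = np.asarray(ids, dtype="<i4")
    means = np.asarray(means, dtype="<u2")
    if ids.shape != means.shape:
        raise ValidationError("ids and means must have the same length")
    n = len(ids)
    header_size = 16 + 3 * 10  # magic + version + nfields + 3 field entries
    off_n = header_size
    off_ids = off_n + 4
    off_means = off_ids + 4 * n
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<q", 3))
        fh.write(struct.pack("<i", 3))
        for code, off in ((_FIELD_N_PROBES, off_n),
                          (_FIELD_ILLUMINA_ID, off_ids),
                          (_FIELD_MEAN, off_means)):
            fh.write(struct.pack("<Hq", code, off))
        fh.write(struct.pack("<i", n))
        fh.write(ids.tobytes())
        fh.write(means.tobytes())


def _lookup(channel: Dict[int, float], address, probe: str, dropped: list) -> float:
    if pd.isna(address):
        dropped.append(probe)
        return np.nan
    val = channel.get(int(address))
    if val is None:
        dropped.append(probe)
        return np.nan
    return val


def read_idat_pair(
    grn_path: Path | str,
    red_path: Path | str,
    manifest: Manifest | Path | str,
    sample_id: str = "sample",
) -> MethylationDataset:
    """Decode a green/red IDAT pair into a single-sample dataset.

    Address conventions: type II probes read U from red and M from green at
    ``address_a``; type I probes read U at ``address_a`` and M at
    ``address_b``, both in their design channel. Control probes read both
    channels at ``address_a``. Addresses missing from the decoded files are
    dropped with a warning and counted in the log.
    """
    from .io import read_manifest

    if not isinstance(manifest, Manifest):
        manifest = read_manifest(manifest)
    t = manifest.table
    if "address_a" not in t.columns:
        raise ValidationError("manifest lacks address_a column required for IDAT decoding")

    grn_raw = read_idat(grn_path)
    red_raw = read_idat(red_path)
    grn = dict(zip(grn_raw["ids"].tolist(), grn_raw["means"].tolist()))
    red = dict(zip(red_raw["ids"].tolist(), red_raw["means"].tolist()))

    dropped: list = []
    is_ctl = t["probe_class"] == "control"
    probes = t.index[~is_ctl]
    U = np.full(len(probes), np.nan)
    M = np.full(len(probes), np.nan)
    for i, p in enumerate(probes):
        row = t.loc[p]
        design = row["channel_design"]
        if design == "typeII":
            U[i] = _lookup(red, row["address_a"], p, dropped)
            M[i] = _lookup(grn, row["address_a"], p, dropped)
        else:
            chan = grn if design == "typeI_green" else red
            U[i] = _lookup(chan, row["address_a"], p, dropped)
            M[i] = _lookup(chan, row.get("address_b"), p, dropped)

    ctl_probes = t.index[is_ctl]
    cg = np.full(len(ctl_probes), np.nan)
    cr = np.full(len(ctl_probes), np.nan)
    for i, p in enumerate(ctl_probes):
        addr = t.loc[p, "address_a"]
        cg[i] = _lookup(grn, addr, p, dropped)
        cr[i] = _lookup(red, addr, p, dropped)

    if dropped:
        logger.warning("read_idat_pair: dropped %d probe lookups with missing addresses",
                       len(dropped))

    samples = pd.DataFrame({"donor_id": [sample_id], "recorded_sex": ["unknown"]},
                           index=pd.Index([sample_id], name="sample_id"))
    return MethylationDataset(
        U=pd.DataFrame({sample_id: U}, index=probes),
        M=pd.DataFrame({sample_id: M}, index=probes),
        controls_grn=pd.DataFrame({sample_id: cg}, index=ctl_probes),
        controls_red=pd.DataFrame({sample_id: cr}, index=ctl_probes),
        samples=samples,
        manifest=manifest,
    )
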