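"""File formats: ERP matrices (CSV + JSON sidecar, EDF), montages, maps, features.

The canonical exchange format for one subject x condition ERP is a plain CSV
matrix (rows = channels, columns = samples, microvolts) next to a JSON
sidecar ``<stem>.json`` carrying ``subject_id``, ``condition``, ``fs``,
``t0_offset_ms``, ``channel_ids`` and ``reference``. EDF epoch files are
accepted read-only.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .erp import ErpWaveform, Montage
from .microstates import MicrostateMaps

SIDECAR_FIELDS = ("subject_id", "condition", "fs", "t0_offset_ms", "channel_ids", "reference")


def write_erp(erp: ErpWaveform, path: str | Path) -> None:
    """Write the CSV matrix and its JSON sidecar."""
    path = Path(path)
    np.savetxt(path, erp.data, delimiter=",", fmt="%.10g")
    sidecar = {
        "subject_id": erp.subject_id,
        "condition": erp.condition,
        "fs": erp.fs,
        "t0_offset_ms": erp.t0_offset,
        "channel_ids": list(erp.channel_ids),
        "reference": erp.reference,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_erp(
    path: str | Path,
    t0_offset_ms: float | None = None,
    subject_id: str = "",
    condition: str = "",
) -> ErpWaveform:
    """Read an ERP from a CSV + sidecar pair, or an EDF epoch file.

    For EDF input the sampling rate and channel labels come from the EDF
    header (potentials are converted to microvolts); subject, condition and
    stimulus-onset offset are taken from the arguments.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path, t0_offset_ms or 0.0, subject_id, condition)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for fieldname in ("fs",):
        if fieldname not in meta:
            raise KeyError(f"sidecar {sidecar_path} is missing required field {fieldname!r}")
    try:
        data = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    channel_ids = tuple(meta.get("channel_ids", ()))
    if channel_ids and len(channel_ids) != data.shape[0]:
        raise ValueError(
            f"{path}: {data.shape[0]} channel rows but sidecar lists {len(channel_ids)} ids"
        )
    return ErpWaveform(
        data=data,
        fs=float(meta["fs"]),
        t0_offset=float(meta.get("t0_offset_ms", 0.0)),
        channel_ids=channel_ids,
        condition=meta.get("condition", condition),
        subject_id=meta.get("subject_id", subject_id),
        reference=meta.get("reference", "other"),
    )


def _read_edf(path: Path, t0_offset_ms: float, subject_id: str, condition: str) -> ErpWaveform:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the optional dependency mne") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return ErpWaveform(
        data=data,
        fs=float(raw.info["sfreq"]),
        t0_offset=t0_offset_ms,
        channel_ids=tuple(raw.ch_names),
        condition=condition,
        subject_id=subject_id,
        reference="other",
    )


def read_erp_dir(erp_dir: str | Path) -> dict[str, dict[str, ErpWaveform]]:
    """Load every ``*.csv`` ERP under a directory into subject -> condition."""
    out: dict[str, dict[str, ErpWaveform]] = {}
    for path in sorted(Path(erp_dir).glob("*.csv")):
        erp = read_erp(path)
        out.setdefault(erp.subject_id, {})[erp.condition] = erp
    return out


def write_montage(montage: Montage, path: str | Path) -> None:
    Path(path).write_text(json.dumps(montage.regions, indent=1, sort_keys=True))


def read_montage(path: str | Path) -> Montage:
    return Montage(json.loads(Path(path).read_text()))


def write_maps(maps: MicrostateMaps, out_dir: str | Path, meta: dict | None = None) -> None:
    """Maps as a CSV (rows = maps, columns = channels) plus JSON metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savetxt(out_dir / "maps.csv", maps.maps, delimiter=",", fmt="%.12g")
    info = {"k": maps.k, "n_channels": maps.n_channels, "source": maps.source}
    info.update(meta or {})
    (out_dir / "maps.json").write_text(json.dumps(info, indent=1, sort_keys=True))


def read_maps(out_dir: str | Path) -> MicrostateMaps:
    out_dir = Path(out_dir)
    m = np.loadtxt(out_dir / "maps.csv", delimiter=",", ndmin=2)
    meta = json.loads((out_dir / "maps.json").read_text())
    return MicrostateMaps(m, source=meta.get("source", ""))


def write_features(features: pd.DataFrame, path: str | Path) -> None:
    features.to_csv(path, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
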