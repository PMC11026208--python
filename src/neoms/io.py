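"""Readers and writers for epochs, map sets and cohort tables.

Epochs travel as tab-delimited text matrices (one column per channel,
one row per sample, a ``# fs=<Hz>`` comment followed by a one-line
header of channel names) or as EDF via :mod:`mne` when it is installed.
Map sets are CSV (rows = maps, columns = channels) with a JSON sidecar
for scalar metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from neoms.epoch import EEGEpoch, NEONATAL_CHANNELS
from neoms.microstates import MapSet
from neoms.synthetic import CohortRecord


def write_matrix(epoch: EEGEpoch, path: str | Path) -> None:
    """Write an epoch as a tab-delimited samples x channels matrix."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={epoch.fs!r}\n")
        if epoch.sleep_state:
            fh.write(f"# sleep_state={epoch.sleep_state}\n")
        fh.write("\t".join(epoch.channel_names) + "\n")
        np.savetxt(fh, epoch.data.T, fmt="%.6f", delimiter="\t")


def read_matrix(path: str | Path, fs: float | None = None) -> EEGEpoch:
    """Read a tab-delimited epoch written by :func:`write_matrix`."""
    path = Path(path)
    sleep_state = None
    with path.open() as fh:
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            if key.strip() == "fs":
                fs = float(val)
            elif key.strip() == "sleep_state":
                sleep_state = val.strip()
            line = fh.readline()
        names = tuple(line.strip().split("\t"))
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if fs is None:
        raise ValueError(f"{path}: sampling rate not in file and not provided")
    return EEGEpoch(data=data.T, fs=fs, channel_names=names, sleep_state=sleep_state)


def read_edf(path: str | Path, channels: tuple[str, ...] = NEONATAL_CHANNELS) -> EEGEpoch:
    """Read an EDF recording, matching channel labels case-insensitively."""
    try:
        import mne
    except ImportError as err:  # pragma: no cover - depends on extras
        raise ImportError("EDF reading requires mne (pip install neoms[edf])") from err
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    lookup = {name.lower(): name for name in raw.ch_names}
    picks = []
    for ch in channels:
        match = lookup.get(ch.lower())
        if match is None:
            raise ValueError(f"channel {ch} not found in {path}")
        picks.append(match)
    data = raw.get_data(picks=picks) * 1e6  # volts -> microvolts
    return EEGEpoch(data=data, fs=float(raw.info["sfreq"]), channel_names=channels)


def write_mapset(mapset: MapSet, path: str | Path, **meta) -> None:
    """CSV of the topographies plus a JSON sidecar of scalar metadata."""
    path = Path(path)
    names = mapset.channel_names or tuple(
        f"ch{i + 1:02d}" for i in range(mapset.n_channels)
    )
    pd.DataFrame(mapset.maps, columns=list(names)).to_csv(path, index=False)
    sidecar = {"k": mapset.k, **meta}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_mapset(path: str | Path) -> MapSet:
    df = pd.read_csv(path)
    return MapSet(df.to_numpy(dtype=float), tuple(df.columns))


def write_cohort(
    cohort: list[tuple[CohortRecord, EEGEpoch]], out_dir: str | Path
) -> Path:
    """Write every epoch as a text matrix plus a cohort CSV linking them."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (rec, epoch) in enumerate(cohort):
        name = f"{rec.subject_id}_{rec.age_group}_{rec.sleep_state}.tsv"
        write_matrix(epoch, out_dir / name)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "ga_weeks": rec.ga_weeks,
                "pma_weeks": rec.pma_weeks,
                "sleep_state": rec.sleep_state,
                "age_group": rec.age_group,
                "epoch_path": name,
                "true_mean_duration_ms": rec.truth.get("mean_duration_ms"),
                "true_hurst": rec.truth.get("hurst_target"),
            }
        )
    table = out_dir / "cohort.csv"
    pd.DataFrame(rows).to_csv(table, index=False)
    return table


def read_cohort(table_path: str | Path) -> list[tuple[CohortRecord, EEGEpoch]]:
    """Load a cohort written by :func:`write_cohort` (or hand-built)."""
    table_path = Path(table_path)
    base = table_path.parent
    df = pd.read_csv(table_path)
    out = []
    for _, row in df.iterrows():
        truth = {}
        if "true_mean_duration_ms" in row and pd.notna(row["true_mean_duration_ms"]):
            truth["mean_duration_ms"] = float(row["true_mean_duration_ms"])
        if "true_hurst" in row and pd.notna(row["true_hurst"]):
            truth["hurst_target"] = float(row["true_hurst"])
        rec = CohortRecord(
            subject_id=str(row["subject_id"]),
            ga_weeks=float(row["ga_weeks"]),
            pma_weeks=float(row["pma_weeks"]),
            sleep_state=str(row["sleep_state"]),
            truth=truth,
        )
        path = base / str(row["epoch_path"])
        if path.suffix.lower() == ".edf":
            epoch = read_edf(path)
        else:
            epoch = read_matrix(path)
        epoch.sleep_state = rec.sleep_state
        out.append((rec, epoch))
    return out
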