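"""Readers and writers for the pipeline's on-disk formats.

EEG: HDF5 (dataset ``trace``; attrs ``fs``, ``period_labels``,
``period_starts``, ``period_ends``) with a two-file CSV fallback.
Spikes: spike-times CSV (unit_id, spike_time_s) + units metadata CSV +
pulses CSV.  Images: single-channel 16-bit TIFF + ground-truth CSV.
Group tables: plain CSV.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .eeg import EEGRecording
from .exceptions import ParameterError
from .spikes import SortedUnit, StimProtocol


# ----------------------------------------------------------------------- EEG


def write_eeg_h5(rec: EEGRecording, path) -> None:
    with h5py.File(path, "w") as f:
        dset = f.create_dataset("trace", data=rec.trace)
        dset.attrs["fs"] = rec.fs
        dset.attrs["period_labels"] = [label for label, _, _ in rec.periods]
        dset.attrs["period_starts"] = [start for _, start, _ in rec.periods]
        dset.attrs["period_ends"] = [end for _, _, end in rec.periods]


def read_eeg_h5(path) -> EEGRecording:
    with h5py.File(path, "r") as f:
        dset = f["trace"]
        labels = [
            l.decode() if isinstance(l, bytes) else str(l)
            for l in dset.attrs["period_labels"]
        ]
        periods = tuple(
            zip(labels, dset.attrs["period_starts"], dset.attrs["period_ends"])
        )
        return EEGRecording(trace=dset[:], fs=float(dset.attrs["fs"]), periods=periods)


def write_eeg_csv(rec: EEGRecording, trace_path, periods_path) -> None:
    """CSV fallback: one file of samples (with fs in the header), one of periods."""
    with open(trace_path, "w") as f:
        f.write(f"# fs_hz={rec.fs}\nvoltage\n")
        np.savetxt(f, rec.trace, fmt="%.10g")
    pd.DataFrame(
        [{"label": l, "start_s": a, "end_s": b} for l, a, b in rec.periods]
    ).to_csv(periods_path, index=False)


def read_eeg_csv(trace_path, periods_path) -> EEGRecording:
    with open(trace_path) as f:
        header = f.readline().strip()
    if not header.startswith("# fs_hz="):
        raise ParameterError(f"{trace_path}: missing '# fs_hz=' header line")
    fs = float(header.split("=", 1)[1])
    trace = pd.read_csv(trace_path, comment="#")["voltage"].to_numpy()
    periods_df = pd.read_csv(periods_path)
    periods = tuple(
        (r["label"], r["start_s"], r["end_s"]) for _, r in periods_df.iterrows()
    )
    return EEGRecording(trace=trace, fs=fs, periods=periods)


# --------------------------------------------------------------------- spikes


def write_spike_data(units: list[SortedUnit], protocol: StimProtocol, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spike_rows = []
    for u in units:
        for t in u.spike_times_s:
            spike_rows.append({"unit_id": u.unit_id, "spike_time_s": t})
    pd.DataFrame(spike_rows, columns=["unit_id", "spike_time_s"]).to_csv(
        out / "spikes.csv", index=False
    )
    pd.DataFrame(
        [
            {
                "unit_id": u.unit_id,
                "region": u.region,
                "trough_to_peak_ms": u.trough_to_peak_ms,
                "isolation_distance": u.isolation_distance,
            }
            for u in units
        ]
    ).to_csv(out / "units.csv", index=False)
    pd.DataFrame(
        {
            "pulse_onset_s": protocol.pulse_onsets_s,
            "pulse_duration_s": protocol.pulse_duration_s,
            "pre_window_s": protocol.pre_window_s,
        }
    ).to_csv(out / "pulses.csv", index=False)


def read_spike_data(
    spikes_path, units_path, pulses_path
) -> tuple[list[SortedUnit], StimProtocol]:
    spikes = pd.read_csv(spikes_path)
    meta = pd.read_csv(units_path)
    pulses = pd.read_csv(pulses_path)
    grouped = spikes.groupby("unit_id")["spike_time_s"]
    units = []
    for _, row in meta.iterrows():
        uid = row["unit_id"]
        times = (
            np.sort(grouped.get_group(uid).to_numpy())
            if uid in grouped.groups
            else np.empty(0)
        )
        units.append(
            SortedUnit(
                unit_id=str(uid),
                region=str(row["region"]),
                spike_times_s=times,
                trough_to_peak_ms=float(row["trough_to_peak_ms"]),
                isolation_distance=float(row["isolation_distance"]),
            )
        )
    protocol = StimProtocol(
        pulse_onsets_s=pulses["pulse_onset_s"].to_numpy(),
        pulse_duration_s=float(pulses["pulse_duration_s"].iloc[0]),
        pre_window_s=float(pulses["pre_window_s"].iloc[0]),
    )
    return units, protocol


# --------------------------------------------------------------------- images


def write_tiff(image: np.ndarray, path) -> None:
    """Write a single-channel intensity image as 16-bit TIFF (values clipped)."""
    data = np.clip(np.rint(np.asarray(image, dtype=float)), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)


def read_tiff(path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def write_ground_truth(ground_truth: pd.DataFrame, path) -> None:
    ground_truth.to_csv(path, index=False)


# ---------------------------------------------------------------- group tables


def write_group_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_group_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
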