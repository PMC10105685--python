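"""File I/O for the standard interchange formats of the analysis chain.

Dose-response tables and puff-event lists travel as CSV, idealizations and
ground-truth event trains as TSV, gating statistics as JSON, linescans as
single-channel grayscale TIFF, and current traces as HDF5 (datasets
``samples`` plus calibration attributes) with an optional flat CSV form.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import tifffile

from .bilayersim import CurrentTrace, EventTrain
from .idealize import ChannelStats, Idealization
from .puffs import LinescanImage, PuffEvent

__all__ = [
    "read_dose_response_csv",
    "write_dose_response_csv",
    "write_idealization_tsv",
    "read_idealization_tsv",
    "write_stats_json",
    "write_event_trains_tsv",
    "save_trace_h5",
    "load_trace_h5",
    "write_trace_csv",
    "save_linescan_tiff",
    "load_linescan_tiff",
    "write_puff_events_csv",
    "read_puff_events_csv",
]


def read_dose_response_csv(path) -> pd.DataFrame:
    """Read a dose-response table with columns x, y[, y_err, n]."""
    df = pd.read_csv(path)
    missing = {"x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"dose-response CSV lacks columns: {sorted(missing)}")
    return df


def write_dose_response_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_idealization_tsv(ideal: Idealization, path) -> None:
    pd.DataFrame(
        {
            "level": ideal.levels,
            "start_s": ideal.starts,
            "duration_s": ideal.durations,
        }
    ).to_csv(path, sep="\t", index=False)


def read_idealization_tsv(path, sample_rate: float, unitary: float,
                          baseline: float = 0.0) -> Idealization:
    df = pd.read_csv(path, sep="\t")
    counts = np.rint(df["duration_s"].to_numpy() * sample_rate).astype(int)
    return Idealization(
        levels=df["level"].to_numpy(int),
        n_samples=counts,
        sample_rate=sample_rate,
        unitary_amplitude=unitary,
        baseline=baseline,
    )


def write_stats_json(stats: ChannelStats, path) -> None:
    payload = {
        "npo": stats.npo,
        "mot_s": stats.mot,
        "mct_s": stats.mct,
        "n_open_events": stats.n_open_events,
        "n_channels": stats.n_channels_est,
        "record_s": stats.record_length,
        "mot_applicable": stats.mot_applicable,
    }
    Path(path).write_text(json.dumps(payload, indent=2, allow_nan=True))


def write_event_trains_tsv(trains: Sequence[EventTrain], path) -> None:
    rows = []
    for ch, train in enumerate(trains):
        for state, start, dur in zip(train.states, train.starts, train.durations):
            rows.append(
                {"channel": ch, "state": int(state), "start_s": start,
                 "duration_s": dur}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def save_trace_h5(trace: CurrentTrace, path) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("samples", data=trace.samples)
        fh.attrs["sample_rate"] = trace.sample_rate
        if trace.config is not None:
            for key, value in asdict(trace.config).items():
                if value is not None:
                    fh.attrs[f"config/{key}"] = value
        for key, value in trace.ligands.items():
            fh.attrs[f"ligand/{key}"] = value


def load_trace_h5(path) -> CurrentTrace:
    with h5py.File(path, "r") as fh:
        samples = fh["samples"][:]
        fs = float(fh.attrs["sample_rate"])
        ligands = {
            k.split("/", 1)[1]: float(v)
            for k, v in fh.attrs.items()
            if k.startswith("ligand/")
        }
    return CurrentTrace(samples=samples, sample_rate=fs, ligands=ligands)


def write_trace_csv(trace: CurrentTrace, path) -> None:
    pd.DataFrame({"time_s": trace.time, "current_pA": trace.samples}).to_csv(
        path, index=False
    )


def save_linescan_tiff(image: LinescanImage, path) -> None:
    tifffile.imwrite(path, image.pixels.astype(np.float32))


def load_linescan_tiff(path, dx: float = 0.63, dt: float = 0.1,
                       cells: Sequence = ()) -> LinescanImage:
    pixels = tifffile.imread(path).astype(float)
    if not cells:
        cells = ((0, pixels.shape[0]),)
    return LinescanImage(pixels, dx=dx, dt=dt, cells=tuple(cells))


def write_puff_events_csv(events: Sequence[PuffEvent], path) -> None:
    pd.DataFrame(
        [
            {
                "cell_id": e.cell_id,
                "position_um": e.position,
                "t_peak_s": e.t_peak,
                "amplitude_dff": e.amplitude,
                "fdhm_s": e.fdhm,
                "ttp_s": e.time_to_peak,
                "rise_s": e.rise_20_80,
                "decay_s": e.decay_80_20,
                "censored": e.censored,
            }
            for e in events
        ]
    ).to_csv(path, index=False)


def read_puff_events_csv(path) -> list[PuffEvent]:
    df = pd.read_csv(path)
    return [
        PuffEvent(
            cell_id=int(r.cell_id),
            position=float(r.position_um),
            t_peak=float(r.t_peak_s),
            amplitude=float(r.amplitude_dff),
            fdhm=float(r.fdhm_s),
            time_to_peak=float(r.ttp_s),
            rise_20_80=float(r.rise_s),
            decay_80_20=float(r.decay_s),
            censored=bool(r.censored),
        )
        for r in df.itertuples()
    ]
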