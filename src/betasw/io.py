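"""File formats: ROI time-series TSV, subject CSV, matrices, EEG readers.

ROI series travel as delimited text (one row per sample, header = ROI
labels); connectivity matrices as square delimited files with a label
header; subject tables and metrics as CSV.  Raw scalp EEG is read from
BrainVision (.vhdr/.vmrk/.eeg) or EDF through MNE; a minimal BrainVision
writer (IEEE float32, multiplexed) is provided because no installed library
exposes one.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, RoiTimeSeries
from .networks import Band
from .preprocess import Recording
from .subjects import SubjectRecord, subjects_from_frame, subjects_to_frame

__all__ = [
    "write_roi_tsv", "read_roi_tsv",
    "write_subjects_csv", "read_subjects_csv",
    "write_matrix", "read_matrix",
    "read_raw", "write_brainvision", "montage_positions",
    "write_json",
]


def write_roi_tsv(roi: RoiTimeSeries, path: str | Path) -> Path:
    path = Path(path)
    roi.to_frame().to_csv(path, sep="\t", index=False,
                          float_format="%.6g")
    return path


def read_roi_tsv(path: str | Path, rate_hz: float) -> RoiTimeSeries:
    frame = pd.read_csv(path, sep="\t")
    return RoiTimeSeries.from_frame(frame, rate_hz)


def write_subjects_csv(subjects: list[SubjectRecord], path: str | Path) -> Path:
    path = Path(path)
    subjects_to_frame(subjects).to_csv(path, index=False)
    return path


def read_subjects_csv(path: str | Path) -> list[SubjectRecord]:
    return subjects_from_frame(pd.read_csv(path))


def write_matrix(cm: ConnectivityMatrix, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(cm.W, index=list(cm.labels),
                 columns=list(cm.labels)).to_csv(path, sep="\t")
    return path


def read_matrix(path: str | Path, band: Band, n_epochs_used: int = 0
                ) -> ConnectivityMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return ConnectivityMatrix(W=frame.to_numpy(), labels=tuple(frame.columns),
                              band=band, n_epochs_used=n_epochs_used)


# ---------------------------------------------------------------------------
# raw EEG
# ---------------------------------------------------------------------------


def read_raw(path: str | Path) -> Recording:
    """Read a BrainVision (.vhdr) or EDF (.edf) recording into uV."""
    import mne

    path = Path(path)
    with mne.utils.use_log_level("error"):
        if path.suffix.lower() == ".vhdr":
            raw = mne.io.read_raw_brainvision(path, preload=True)
        elif path.suffix.lower() == ".edf":
            raw = mne.io.read_raw_edf(path, preload=True)
        else:
            raise ValueError(f"unsupported raw format {path.suffix!r}")
    data = raw.get_data() * 1e6  # volts -> microvolts
    if np.isnan(data).any():
        raise ValueError("raw recording contains NaNs")
    return Recording(data, float(raw.info["sfreq"]),
                     tuple(raw.ch_names))


def write_brainvision(rec: Recording, basename: str | Path) -> Path:
    """Write a BrainVision triplet (.vhdr/.vmrk/.eeg), IEEE float32, uV."""
    base = Path(basename)
    base.parent.mkdir(parents=True, exist_ok=True)
    stem = base.name
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))
    interval_us = 1e6 / rec.rate_hz
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        f"MarkerFile={stem}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={interval_us:g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    lines += [f"Ch{i + 1}={lab},,1,µV"
              for i, lab in enumerate(rec.channel_labels)]
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")
    vmrk.write_text("\n".join([
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,0",
    ]) + "\n", encoding="utf-8")
    eeg.write_bytes(np.ascontiguousarray(rec.data.T, dtype="<f4").tobytes())
    return vhdr


def montage_positions(labels: tuple[str, ...]) -> dict:
    """Head-frame 3-D positions for 10-20 labels, from the standard montage."""
    import mne

    try:
        montage = mne.channels.make_standard_montage("colin27_1020")
    except ValueError:  # older montage registry
        montage = mne.channels.make_standard_montage("standard_1020")
    pos = montage.get_positions()["ch_pos"]
    missing = [lab for lab in labels if lab not in pos]
    if missing:
        raise ValueError(f"labels not in the 10-20 montage: {missing}")
    return {lab: np.asarray(pos[lab], dtype=float) for lab in labels}


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(obj, indent=2, default=str) + "\n")
    tmp.replace(path)
    return path
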