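"""Reading and writing EEG records and cohort directories.

Supported record formats: EDF (via :mod:`mne`), plain CSV and NPY matrices
(channels × samples).  Cohort directories follow the layout written by
:meth:`microfuse.synth.Cohort.save`: one NPY per subject plus a
``metadata.csv`` with subject id, group, sampling rate and channel count.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .records import EEGRecord

__all__ = ["read_record", "write_record", "read_cohort_dir"]


def read_record(
    path: str | Path,
    fs_hz: float | None = None,
    subject_id: str | None = None,
    group_label: str = "unknown",
) -> EEGRecord:
    """Load one record from ``.edf``, ``.csv`` or ``.npy``.

    ``fs_hz`` is required for CSV/NPY (the formats carry no rate); EDF
    supplies its own rate and channel names.
    """
    path = Path(path)
    sid = subject_id or path.stem
    suffix = path.suffix.lower()
    if suffix == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return EEGRecord(
            data=raw.get_data() * 1e6,  # volts -> microvolts
            fs_hz=float(raw.info["sfreq"]),
            channel_names=list(raw.ch_names),
            subject_id=sid,
            group_label=group_label,
        )
    if suffix == ".npy":
        data = np.load(path)
    elif suffix == ".csv":
        data = pd.read_csv(path, header=None).to_numpy(dtype=float)
    else:
        raise ValueError(f"unsupported record format: {suffix}")
    if fs_hz is None:
        raise ValueError("fs_hz required for CSV/NPY records")
    return EEGRecord(data=data, fs_hz=fs_hz, subject_id=sid, group_label=group_label)


def write_record(rec: EEGRecord, path: str | Path) -> None:
    """Write the data matrix as NPY or CSV (metadata is the caller's job)."""
    path = Path(path)
    if path.suffix.lower() == ".npy":
        np.save(path, rec.data)
    elif path.suffix.lower() == ".csv":
        pd.DataFrame(rec.data).to_csv(path, header=False, index=False)
    else:
        raise ValueError(f"unsupported record format: {path.suffix}")


def read_cohort_dir(input_dir: str | Path) -> list[EEGRecord]:
    """Load all subjects listed in a cohort directory's ``metadata.csv``."""
    input_dir = Path(input_dir)
    meta_path = input_dir / "metadata.csv"
    if not meta_path.exists():
        raise ValueError(f"missing metadata.csv in {input_dir}")
    meta = pd.read_csv(meta_path)
    records = []
    for _, row in meta.iterrows():
        sid = str(row["subject_id"])
        npy = input_dir / f"{sid}.npy"
        csv = input_dir / f"{sid}.csv"
        path = npy if npy.exists() else csv
        if not path.exists():
            raise ValueError(f"missing data file for subject {sid}")
        records.append(read_record(path, fs_hz=float(row["fs_hz"]), subject_id=sid,
                                   group_label=str(row["group"])))
    return records
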