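"""EEG record container and 10-20 montage constants.

An :class:`EEGRecord` holds one subject's multichannel recording as a
``(n_channels, n_samples)`` array of scalp potentials (µV by convention),
together with the sampling rate, channel names and a group label.  All
pipeline stages consume and produce this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: The 19-channel international 10-20 montage used by the reference dataset
#: (earlobe-referenced clinical layouts typically record exactly these).
TEN_TWENTY_19: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: Idealised 2-D electrode positions on the unit disc (x: left→right,
#: y: posterior→anterior).  Used only to construct synthetic canonical
#: topographies; not a substitute for digitised positions.
TEN_TWENTY_19_XY: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.45, 0.52), "Fz": (0.0, 0.50),
    "F4": (0.45, 0.52), "F8": (0.81, 0.59),
    "T3": (-1.0, 0.0), "C3": (-0.50, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.50, 0.0), "T4": (1.0, 0.0),
    "T5": (-0.81, -0.59), "P3": (-0.45, -0.52), "Pz": (0.0, -0.50),
    "P4": (0.45, -0.52), "T6": (0.81, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}


@dataclass
class EEGRecord:
    """One subject's channels × samples EEG matrix with metadata.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)``.
    fs_hz
        Sampling rate in Hz (must be positive).
    channel_names
        Ordered channel labels; defaults to ``ch00 .. chNN``.
    subject_id
        Identifier used for subject-independent cross-validation.
    group_label
        ``"case"``, ``"control"`` or ``"unknown"``.
    """

    data: np.ndarray
    fs_hz: float
    channel_names: list[str] = field(default_factory=list)
    subject_id: str = "unknown"
    group_label: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_channels, n_samples)")
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if self.n_samples < 1:
            raise ValueError("need at least 1 sample")
        if not self.fs_hz > 0:
            raise ValueError("fs_hz must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length mismatch")
        if self.group_label not in ("case", "control", "unknown"):
            raise ValueError(f"bad group_label {self.group_label!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def with_data(self, data: np.ndarray) -> "EEGRecord":
        """Copy of this record with a new data matrix (same metadata)."""
        return replace(self, data=np.asarray(data, dtype=float))

    def assert_finite(self) -> None:
        if not np.isfinite(self.data).all():
            raise ValueError(f"record {self.subject_id}: non-finite samples")
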