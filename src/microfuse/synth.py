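"""Synthetic EEG cohorts with known microstate ground truth.

The generator inverts the microstate model: a semi-Markov state sequence
(geometric run lengths, first-order transitions) selects one of K fixed
scalp topographies at every sample; the active map is scaled by a smoothly
varying positive amplitude (so that global-field-power peaks exist) and
i.i.d. Gaussian sensor noise is added.  Because the generating templates,
durations and transition matrix are known, every downstream stage —
backfitting, temporal statistics, group comparison, classification — can be
tested against ground truth.

Group differences are encoded through per-state duration overrides and
transition-row overrides, emulating the case/control pattern reported for
attention-deficit cohorts: activation-state B lengthened and over-visited,
integration-state C shortened and under-visited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .records import EEGRecord, TEN_TWENTY_19

__all__ = [
    "MicrostateGroundTruth",
    "CohortSpec",
    "Cohort",
    "generate_templates",
    "uniform_transition_matrix",
    "simulate_state_sequence",
    "amplitude_series",
    "synthesize_eeg",
    "apply_group_deltas",
    "default_control_ground_truth",
    "DEFAULT_CASE_DELTAS",
    "make_case_ground_truth",
    "generate_cohort",
]


@dataclass
class MicrostateGroundTruth:
    """Generating parameters of one group's microstate process.

    ``templates`` are K zero-channel-mean, unit-norm maps; ``transition_matrix``
    is row-stochastic with a structurally zero diagonal; ``mean_durations_ms``
    are the expected run lengths per state; ``noise_sd`` is the per-channel
    sensor-noise SD relative to the unit-GFP signal scale.
    """

    templates: np.ndarray
    transition_matrix: np.ndarray
    mean_durations_ms: np.ndarray
    noise_sd: float
    seed: int = 0

    def __post_init__(self) -> None:
        self.templates = np.asarray(self.templates, dtype=float)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.mean_durations_ms = np.asarray(self.mean_durations_ms, dtype=float)
        K = self.templates.shape[0]
        P = self.transition_matrix
        if P.shape != (K, K):
            raise ValueError("transition_matrix shape mismatch")
        if np.any(np.diag(P) != 0.0):
            raise ValueError("transition_matrix diagonal must be exactly 0")
        if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition rows must sum to 1")
        if np.any(P < 0):
            raise ValueError("transition probabilities must be nonnegative")
        if self.mean_durations_ms.shape != (K,) or np.any(self.mean_durations_ms <= 0):
            raise ValueError("mean_durations_ms must be K positive values")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        means = self.templates.mean(axis=1)
        norms = np.linalg.norm(self.templates, axis=1)
        if np.any(np.abs(means) > 1e-9) or np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("templates must be zero channel-mean and unit-norm")

    @property
    def n_states(self) -> int:
        return self.templates.shape[0]

    @property
    def n_channels(self) -> int:
        return self.templates.shape[1]


@dataclass
class CohortSpec:
    """Shape of a two-group synthetic cohort.

    Defaults emulate a two-group child EEG study: ~60 subjects per group,
    19 channels at 128 Hz, one-minute records.  ``group_deltas`` holds the
    case-group overrides (state durations and transition rows) applied on
    top of the control ground truth.
    """

    n_subjects_per_group: int = 60
    record_seconds: float = 60.0
    fs_hz: float = 128.0
    group_deltas: dict | None = None

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1:
            raise ValueError("n_subjects_per_group must be >= 1")
        if not self.fs_hz > 0:
            raise ValueError("fs_hz must be positive")
        if not self.record_seconds > 0:
            raise ValueError("record_seconds must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.record_seconds * self.fs_hz))


@dataclass
class Cohort:
    """Generated records plus their ground-truth state sequences."""

    records: list[EEGRecord]
    true_labels: dict[str, np.ndarray]
    gt_control: MicrostateGroundTruth
    gt_case: MicrostateGroundTruth

    def save(self, out_dir: str | Path) -> None:
        """Write one NPY per subject, a metadata CSV and a ground-truth JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = ["subject_id,group,fs_hz,n_channels"]
        for rec in self.records:
            np.save(out / f"{rec.subject_id}.npy", rec.data)
            np.save(out / f"{rec.subject_id}_labels.npy",
                    self.true_labels[rec.subject_id])
            rows.append(f"{rec.subject_id},{rec.group_label},{rec.fs_hz},{rec.n_channels}")
        (out / "metadata.csv").write_text("\n".join(rows) + "\n")
        gt = {
            name: {
                "templates": g.templates.tolist(),
                "transition_matrix": g.transition_matrix.tolist(),
                "mean_durations_ms": g.mean_durations_ms.tolist(),
                "noise_sd": g.noise_sd,
                "seed": g.seed,
            }
            for name, g in (("control", self.gt_control), ("case", self.gt_case))
        }
        (out / "ground_truth.json").write_text(json.dumps(gt))


def generate_templates(n_channels: int, K: int, seed: int) -> np.ndarray:
    """Draw K mutually near-orthogonal, zero-mean, unit-norm channel maps.

    A Gaussian matrix is projected onto the zero-channel-mean subspace
    (average-reference convention) and orthonormalised by QR, so pairwise
    spatial correlations are ~0 and certainly below 0.5 in magnitude.
    Deterministic for a fixed seed.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > n_channels:
        raise ValueError(f"K={K} exceeds n_channels={n_channels}")
    rng = np.random.default_rng(seed)
    M = rng.standard_normal((n_channels, K))
    M -= M.mean(axis=0, keepdims=True)
    Q, _ = np.linalg.qr(M)
    templates = Q.T[:K]
    # deterministic sign convention: largest-magnitude channel positive
    for k in range(K):
        j = int(np.argmax(np.abs(templates[k])))
        if templates[k, j] < 0:
            templates[k] = -templates[k]
    templates -= templates.mean(axis=1, keepdims=True)
    templates /= np.linalg.norm(templates, axis=1, keepdims=True)
    C = np.abs(templates @ templates.T - np.eye(K))
    if C.max() >= 0.5:  # pragma: no cover - QR keeps correlations ~0
        raise RuntimeError("template correlations too high; degenerate montage")
    return templates


def uniform_transition_matrix(K: int) -> np.ndarray:
    """Row-stochastic matrix with zero diagonal and uniform off-diagonal."""
    P = np.full((K, K), 1.0 / (K - 1))
    np.fill_diagonal(P, 0.0)
    return P


def simulate_state_sequence(
    gt: MicrostateGroundTruth, n_samples: int, fs_hz: float, seed: int
) -> np.ndarray:
    """Simulate the semi-Markov state sequence.

    Run lengths are geometric (support >= 1 sample) with mean
    ``mean_durations_ms * fs / 1000`` per state — the maximum-entropy choice
    consistent with a first-order chain; successive states follow the
    transition matrix.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    K = gt.n_states
    mean_samples = np.maximum(gt.mean_durations_ms * fs_hz / 1000.0, 1.0)
    p_end = 1.0 / mean_samples
    labels = np.empty(n_samples, dtype=np.int64)
    state = int(rng.integers(K))
    pos = 0
    while pos < n_samples:
        run = int(rng.geometric(p_end[state]))
        end = min(pos + run, n_samples)
        labels[pos:end] = state
        pos = end
        state = int(rng.choice(K, p=gt.transition_matrix[state]))
    return labels


def amplitude_series(
    n_samples: int,
    fs_hz: float,
    seed: int,
    sd: float = 0.3,
    smooth_ms: float = 50.0,
) -> np.ndarray:
    """Rectified smoothed Gaussian process with mean ~1.

    Gives the per-sample map strength a slow positive modulation so the
    global field power has well-defined peaks (constant amplitude would
    make peak picking degenerate).
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n_samples)
    sigma = max(smooth_ms * fs_hz / 1000.0, 1.0)
    x = gaussian_filter1d(x, sigma, mode="reflect")
    s = x.std()
    if s > 0:
        x = x / s * sd
    return np.abs(1.0 + x)


def synthesize_eeg(
    gt: MicrostateGroundTruth,
    labels: np.ndarray,
    amplitudes: np.ndarray,
    seed: int,
    fs_hz: float = 128.0,
    channel_names: list[str] | None = None,
    subject_id: str = "synthetic",
    group_label: str = "unknown",
) -> EEGRecord:
    """Render ``V(t) = a(t) * T_label(t) + noise`` as an EEG record.

    The noise is i.i.d. Gaussian per channel, re-projected to zero channel
    mean so the average-reference invariant of the signal part is preserved
    exactly.  With ``noise_sd=0`` every sample map is collinear with its
    active template, so backfitting recovers the labels exactly.
    """
    labels = np.asarray(labels)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if labels.shape != amplitudes.shape:
        raise ValueError("labels and amplitudes must have equal length")
    if np.any(amplitudes <= 0):
        raise ValueError("amplitudes must be positive")
    rng = np.random.default_rng(seed)
    data = (gt.templates[labels] * amplitudes[:, None]).T  # (n_ch, n)
    if gt.noise_sd > 0:
        noise = rng.standard_normal(data.shape) * gt.noise_sd
        noise -= noise.mean(axis=0, keepdims=True)
        data = data + noise
    if channel_names is None and gt.n_channels == len(TEN_TWENTY_19):
        channel_names = list(TEN_TWENTY_19)
    return EEGRecord(
        data=data,
        fs_hz=fs_hz,
        channel_names=channel_names or [],
        subject_id=subject_id,
        group_label=group_label,
    )


def apply_group_deltas(gt: MicrostateGroundTruth, deltas: dict) -> MicrostateGroundTruth:
    """Apply per-state duration and transition-row overrides.

    ``deltas`` may contain ``"durations_ms": {state_index: value}`` and
    ``"transition_rows": {state_index: row}``; overridden rows must stay
    row-stochastic with a zero diagonal (validated on construction).
    """
    durations = gt.mean_durations_ms.copy()
    for k, v in (deltas.get("durations_ms") or {}).items():
        durations[int(k)] = float(v)
    P = gt.transition_matrix.copy()
    for i, row in (deltas.get("transition_rows") or {}).items():
        P[int(i)] = np.asarray(row, dtype=float)
    return MicrostateGroundTruth(
        templates=gt.templates,
        transition_matrix=P,
        mean_durations_ms=durations,
        noise_sd=gt.noise_sd,
        seed=gt.seed,
    )


def default_control_ground_truth(
    n_channels: int = 19,
    K: int = 4,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> MicrostateGroundTruth:
    """Control-group process: 80 ms states, uniform transitions.

    ``noise_sd=0.05`` against a unit-norm template (per-channel signal RMS
    ≈ 1/√19 ≈ 0.23 at mean amplitude 1) gives an SNR of roughly 5.
    """
    return MicrostateGroundTruth(
        templates=generate_templates(n_channels, K, seed),
        transition_matrix=uniform_transition_matrix(K),
        mean_durations_ms=np.full(K, 80.0),
        noise_sd=noise_sd,
        seed=seed,
    )


#: Case-group overrides for a 4-state A/B/C/D process (indices 0..3):
#: state B lengthened (110 ms) and over-targeted, state C shortened (55 ms)
#: and under-targeted — transitions into B rise (A→B, D→B) while transitions
#: into C fall (A→C, B→C, D→C).
DEFAULT_CASE_DELTAS: dict = {
    "durations_ms": {1: 110.0, 2: 55.0},
    "transition_rows": {
        0: [0.0, 0.45, 0.20, 0.35],
        1: [0.40, 0.0, 0.18, 0.42],
        3: [0.35, 0.45, 0.20, 0.0],
    },
}


def make_case_ground_truth(
    gt_control: MicrostateGroundTruth, deltas: dict | None = None
) -> MicrostateGroundTruth:
    """Case-group ground truth from control plus (default) group deltas."""
    return apply_group_deltas(gt_control, DEFAULT_CASE_DELTAS if deltas is None else deltas)


def generate_cohort(
    spec: CohortSpec,
    gt_control: MicrostateGroundTruth,
    gt_case: MicrostateGroundTruth,
    seed: int,
) -> Cohort:
    """Generate a two-group cohort of EEG records with known state labels.

    Every subject receives an independent child seed from a single
    ``SeedSequence``, so cohorts are bit-identical for a fixed seed.
    """
    n = spec.n_samples
    records: list[EEGRecord] = []
    true_labels: dict[str, np.ndarray] = {}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * spec.n_subjects_per_group)
    idx = 0
    for group, gt in (("control", gt_control), ("case", gt_case)):
        for j in range(spec.n_subjects_per_group):
            sub_ss = children[idx]
            idx += 1
            s_lab, s_amp, s_eeg = [int(c.generate_state(1)[0] % (2**31)) for c in sub_ss.spawn(3)]
            labels = simulate_state_sequence(gt, n, spec.fs_hz, s_lab)
            amps = amplitude_series(n, spec.fs_hz, s_amp)
            sid = f"{'ctrl' if group == 'control' else 'case'}_{j:03d}"
            rec = synthesize_eeg(
                gt, labels, amps, s_eeg, fs_hz=spec.fs_hz,
                subject_id=sid, group_label=group,
            )
            records.append(rec)
            true_labels[sid] = labels
    return Cohort(records=records, true_labels=true_labels,
                  gt_control=gt_control, gt_case=gt_case)
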