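"""EEG microstate analysis: GFP, peak picking, polarity-invariant modified
K-means clustering, two-level (subject → group) templates, alignment to
reference maps, backfitting, and the 28-dimensional dynamic feature vector.

Model
-----
Spontaneous EEG is segmented into brief periods of quasi-stable scalp
topography.  The global field power

    GFP(t) = sqrt( (1/N) * sum_i (V_i(t) - Vbar(t))^2 )

is the spatial SD of the instantaneous map; its local maxima are moments of
high topographic signal-to-noise and supply the frames used for clustering.
The modified K-means is polarity invariant: assignment maximises the
*squared* spatial correlation between a frame and a template, and each
template update is the dominant eigenvector of its assigned frames'
scatter matrix (the map direction explaining most variance regardless of
sign).  Model quality is measured by the global explained variance

    GEV_k = sum_{t in S_k} corr^2(V(t), T_k) * GFP(t)^2 / sum_t GFP(t)^2.

Dynamic features per state: mean duration (ms), time coverage, occurrence
rate (runs/s), the 12 off-diagonal run-boundary transition probabilities,
and the 4 GEV values — 28 numbers per labelled segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
import bisect
import itertools
import json

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.signal import find_peaks

from .records import EEGRecord, TEN_TWENTY_19, TEN_TWENTY_19_XY

__all__ = [
    "GFPSeries",
    "MicrostateModel",
    "MicrostateFeatures",
    "SequenceSummary",
    "compute_gfp",
    "detect_gfp_peaks",
    "cluster_templates",
    "two_level_cluster",
    "align_to_reference",
    "backfit",
    "smooth_labels",
    "summarize",
    "compute_gev",
    "feature_vector",
    "canonical_reference_templates",
    "STATE_NAMES",
    "transition_feature_names",
]

STATE_NAMES = ("A", "B", "C", "D")


@dataclass
class GFPSeries:
    values: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("GFP values must be nonnegative")


@dataclass
class MicrostateModel:
    """K aligned templates plus the per-sample label sequence and GEV."""

    templates: np.ndarray                      # (K, n_ch) zero-mean unit-norm
    labels: np.ndarray | None = None
    gev_per_state: np.ndarray | None = None

    @property
    def K(self) -> int:
        return self.templates.shape[0]


# ---------------------------------------------------------------------------
# GFP and peaks
# ---------------------------------------------------------------------------

def compute_gfp(rec: EEGRecord) -> GFPSeries:
    """Spatial standard deviation of the scalp map at each sample."""
    centered = rec.data - rec.data.mean(axis=0, keepdims=True)
    return GFPSeries(np.sqrt((centered ** 2).mean(axis=0)), rec.fs_hz)


def detect_gfp_peaks(gfp: GFPSeries, min_separation_ms: float = 10.0) -> np.ndarray:
    """Strict local maxima of the GFP at least ``min_separation_ms`` apart.

    On conflicts the larger peak wins; equal peaks keep the earlier index.
    """
    if len(gfp.values) < 3:
        return np.array([], dtype=int)
    distance = max(1, int(round(min_separation_ms * gfp.fs_hz / 1000.0)))
    candidates, _ = find_peaks(gfp.values)
    # greedy by height (earlier index wins ties), enforcing the separation
    order = sorted(candidates, key=lambda i: (-gfp.values[i], i))
    kept: list[int] = []
    for i in order:
        pos = bisect.bisect_left(kept, i)
        left_ok = pos == 0 or i - kept[pos - 1] >= distance
        right_ok = pos == len(kept) or kept[pos] - i >= distance
        if left_ok and right_ok:
            kept.insert(pos, i)
    return np.array(kept, dtype=int)


# ---------------------------------------------------------------------------
# polarity-invariant clustering
# ---------------------------------------------------------------------------

def _normalize_maps(maps: np.ndarray) -> np.ndarray:
    """Zero channel-mean, unit L2 norm per map (rows)."""
    m = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return m / norms


def _fix_sign(t: np.ndarray) -> np.ndarray:
    j = int(np.argmax(np.abs(t)))
    return -t if t[j] < 0 else t


def _dominant_map(maps: np.ndarray) -> np.ndarray:
    """First principal direction of a set of maps (polarity-agnostic mean)."""
    scatter = maps.T @ maps
    vals, vecs = np.linalg.eigh(scatter)
    return _fix_sign(vecs[:, -1])


def _cluster_gev(maps_n: np.ndarray, power: np.ndarray, templates: np.ndarray,
                 assign: np.ndarray) -> float:
    corr = np.einsum("ij,ij->i", maps_n, templates[assign])
    return float((corr ** 2 * power).sum() / power.sum())


def cluster_templates(
    peak_maps: np.ndarray,
    K: int = 4,
    n_init: int = 10,
    max_iter: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Polarity-invariant modified K-means on GFP-peak maps.

    Frames are assigned to the template maximising squared spatial
    correlation; templates are re-estimated as the dominant eigenvector of
    their assigned frames.  The best of ``n_init`` seeded restarts (by
    explained variance on the peak maps, GFP²-weighted) is returned, with
    templates zero-mean, unit-norm and deterministically sign-fixed.
    """
    peak_maps = np.asarray(peak_maps, dtype=float)
    if peak_maps.ndim != 2 or peak_maps.shape[0] < K:
        raise ValueError(f"need at least K={K} peak maps")
    power = (np.linalg.norm(peak_maps - peak_maps.mean(axis=1, keepdims=True),
                            axis=1) ** 2)
    power = np.maximum(power, 1e-30)
    maps_n = _normalize_maps(peak_maps)
    rng = np.random.default_rng(seed)

    best_templates, best_score = None, -np.inf
    for _ in range(n_init):
        idx = rng.choice(len(maps_n), size=K, replace=False)
        templates = maps_n[idx].copy()
        assign = np.full(len(maps_n), -1)
        for _ in range(max_iter):
            corr = maps_n @ templates.T
            new_assign = np.argmax(corr ** 2, axis=1)
            if np.array_equal(new_assign, assign):
                break
            assign = new_assign
            for k in range(K):
                members = maps_n[assign == k]
                if len(members) == 0:
                    # re-seed empty cluster with the worst-fit map
                    fit = np.max((maps_n @ templates.T) ** 2, axis=1)
                    templates[k] = maps_n[np.argmin(fit)]
                else:
                    templates[k] = _dominant_map(members)
            templates = _normalize_maps(templates)
        score = _cluster_gev(maps_n, power, templates, assign)
        if score > best_score:
            best_score, best_templates = score, templates.copy()
    return np.array([_fix_sign(t) for t in best_templates])


def two_level_cluster(
    individual_template_sets: list[np.ndarray],
    K: int = 4,
    n_init: int = 10,
    max_iter: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Group-level templates: pool subject templates, re-cluster the pool."""
    if not individual_template_sets:
        raise ValueError("need at least one subject's template set")
    pool = np.vstack(individual_template_sets)
    return cluster_templates(pool, K=K, n_init=n_init, max_iter=max_iter, seed=seed)


# ---------------------------------------------------------------------------
# alignment, backfitting
# ---------------------------------------------------------------------------

def align_to_reference(
    templates: np.ndarray, reference_templates: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimally match templates to reference maps by total |correlation|.

    Solves the assignment problem exactly (Hungarian algorithm, equal to
    the exhaustive K! search), then flips signs so each aligned template
    correlates positively with its reference.  Returns
    ``(aligned_templates, permutation, signs)`` where
    ``aligned[j] = signs[j] * templates[permutation[j]]`` corresponds to
    reference map ``j`` (order A, B, C, D).
    """
    templates = _normalize_maps(np.asarray(templates, dtype=float))
    reference = _normalize_maps(np.asarray(reference_templates, dtype=float))
    if templates.shape[1] != reference.shape[1]:
        raise ValueError("channel count mismatch with reference")
    if templates.shape[0] != reference.shape[0]:
        raise ValueError("K mismatch with reference")
    corr = templates @ reference.T                      # (K_t, K_r)
    rows, cols = linear_sum_assignment(-np.abs(corr))
    perm = np.empty(len(rows), dtype=int)
    perm[cols] = rows                                   # template index per reference slot
    signs = np.sign(corr[perm, np.arange(len(perm))])
    signs[signs == 0] = 1.0
    aligned = templates[perm] * signs[:, None]
    return aligned, perm, signs


def backfit(rec: EEGRecord, templates: np.ndarray) -> np.ndarray:
    """Label every sample with the template of maximal squared correlation.

    Scale- and polarity-invariant; ties resolve to the lowest state index.
    """
    maps_n = _normalize_maps(rec.data.T)
    templates = _normalize_maps(np.asarray(templates, dtype=float))
    corr = maps_n @ templates.T
    return np.argmax(corr ** 2, axis=1)


def smooth_labels(labels: np.ndarray, fs_hz: float, min_duration_ms: float) -> np.ndarray:
    """Optional minimum-run smoothing: runs shorter than the minimum are
    absorbed into the preceding run (the first run is extended forward)."""
    labels = np.asarray(labels).copy()
    min_len = max(1, int(round(min_duration_ms * fs_hz / 1000.0)))
    if min_len <= 1:
        return labels
    changed = True
    while changed:
        changed = False
        starts, lengths, values = _runs(labels)
        for i, (s, ln) in enumerate(zip(starts, lengths)):
            if ln < min_len and len(starts) > 1:
                fill = values[i - 1] if i > 0 else values[i + 1]
                labels[s:s + ln] = fill
                changed = True
                break
    return labels


# ---------------------------------------------------------------------------
# temporal statistics
# ---------------------------------------------------------------------------

def _runs(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Maximal constant segments: (start indices, lengths, values)."""
    labels = np.asarray(labels)
    n = len(labels)
    boundaries = np.nonzero(np.diff(labels) != 0)[0] + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n]))
    return starts, ends - starts, labels[starts]


@dataclass
class SequenceSummary:
    """Run statistics of a label sequence (durations in ms)."""

    duration_ms: np.ndarray
    coverage: np.ndarray
    occurrence_per_s: np.ndarray
    transition_matrix: np.ndarray      # (K, K), zero diagonal, rows sum to 1 or 0
    occurred: np.ndarray               # bool per state
    K: int
    fs_hz: float


def summarize(labels: np.ndarray, fs_hz: float, K: int = 4) -> SequenceSummary:
    """Mean duration, coverage, occurrence rate and run-boundary transition
    probabilities of a state sequence.

    Transitions are counted between successive *runs* (so the diagonal is
    structurally zero).  States that never occur get zero duration,
    coverage, occurrence and an all-zero outgoing row, and are flagged via
    ``occurred``.
    """
    labels = np.asarray(labels)
    if len(labels) < 1:
        raise ValueError("empty label sequence")
    starts, lengths, values = _runs(labels)
    duration = np.zeros(K)
    coverage = np.zeros(K)
    occurrence = np.zeros(K)
    occurred = np.zeros(K, dtype=bool)
    total_s = len(labels) / fs_hz
    for k in range(K):
        runs_k = lengths[values == k]
        if len(runs_k):
            occurred[k] = True
            duration[k] = runs_k.mean() * 1000.0 / fs_hz
            coverage[k] = runs_k.sum() / len(labels)
            occurrence[k] = len(runs_k) / total_s
    counts = np.zeros((K, K))
    np.add.at(counts, (values[:-1], values[1:]), 1.0)
    np.fill_diagonal(counts, 0.0)
    P = np.zeros((K, K))
    row_sums = counts.sum(axis=1)
    nz = row_sums > 0
    P[nz] = counts[nz] / row_sums[nz, None]
    return SequenceSummary(duration, coverage, occurrence, P, occurred, K, fs_hz)


def compute_gev(
    rec: EEGRecord,
    labels: np.ndarray,
    templates: np.ndarray,
    gfp: GFPSeries | None = None,
) -> np.ndarray:
    """Global explained variance per state (GFP²-weighted squared spatial
    correlation between each sample and its assigned template)."""
    if gfp is None:
        gfp = compute_gfp(rec)
    g2 = gfp.values ** 2
    denom = g2.sum()
    if denom <= 0:
        raise ValueError("all-zero GFP: GEV undefined")
    maps_n = _normalize_maps(rec.data.T)
    templates = _normalize_maps(np.asarray(templates, dtype=float))
    corr2 = (np.einsum("ij,ij->i", maps_n, templates[labels])) ** 2
    K = templates.shape[0]
    gev = np.zeros(K)
    for k in range(K):
        sel = labels == k
        gev[k] = (corr2[sel] * g2[sel]).sum() / denom
    return gev


# ---------------------------------------------------------------------------
# 28-D feature vector
# ---------------------------------------------------------------------------

def transition_feature_names(K: int = 4) -> list[str]:
    names = []
    for i, j in itertools.product(range(K), range(K)):
        if i != j:
            names.append(f"trans_{STATE_NAMES[i]}_{STATE_NAMES[j]}")
    return names


@dataclass
class MicrostateFeatures:
    """Ordered 28-D vector: duration(4) + coverage(4) + occurrence(4)
    + transitions(12, row-major without diagonal) + GEV(4)."""

    values: np.ndarray
    names: list[str]
    occurred: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


def feature_vector(summary: SequenceSummary, gev: np.ndarray) -> MicrostateFeatures:
    """Concatenate the dynamic statistics into the fixed 28-D order."""
    K = summary.K
    trans = np.array(
        [summary.transition_matrix[i, j]
         for i, j in itertools.product(range(K), range(K)) if i != j]
    )
    values = np.concatenate(
        [summary.duration_ms, summary.coverage, summary.occurrence_per_s,
         trans, np.asarray(gev, dtype=float)]
    )
    names = (
        [f"duration_{s}" for s in STATE_NAMES[:K]]
        + [f"coverage_{s}" for s in STATE_NAMES[:K]]
        + [f"occurrence_{s}" for s in STATE_NAMES[:K]]
        + transition_feature_names(K)
        + [f"gev_{s}" for s in STATE_NAMES[:K]]
    )
    return MicrostateFeatures(values=values, names=names, occurred=summary.occurred)


# ---------------------------------------------------------------------------
# reference maps
# ---------------------------------------------------------------------------

def canonical_reference_templates(
    channel_names: list[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Synthetic approximations of the four canonical topographies A-D.

    Loaded from a packaged JSON built from idealised 10-20 electrode
    geometry: A and B are the two diagonal gradients, C the
    anterior-posterior gradient, D a fronto-central extremum.  These are
    *constructed* stand-ins for published normative maps (which are not
    redistributable here) and are user-replaceable: any ``(4, n_ch)``
    array can be passed wherever a reference is accepted.
    """
    with resources.files("microfuse.data").joinpath(
        "reference_templates_synthetic_1020_19ch.json"
    ).open() as fh:
        payload = json.load(fh)
    ref_channels = payload["channel_names"]
    maps = np.asarray(payload["templates"], dtype=float)
    if channel_names is None:
        return maps, ref_channels
    try:
        order = [ref_channels.index(c) for c in channel_names]
    except ValueError as e:
        raise ValueError(f"channel not in reference montage: {e}") from e
    return _normalize_maps(maps[:, order]), list(channel_names)


def build_reference_payload() -> dict:
    """Construct the synthetic canonical maps from 10-20 geometry.

    Used once to generate the packaged JSON; kept as code so the artifact
    is reproducible.
    """
    xs = np.array([TEN_TWENTY_19_XY[c][0] for c in TEN_TWENTY_19])
    ys = np.array([TEN_TWENTY_19_XY[c][1] for c in TEN_TWENTY_19])
    maps = np.stack([
        0.85 * xs + 0.53 * ys,                         # A: left-posterior -> right-anterior
        -0.85 * xs + 0.53 * ys,                        # B: right-posterior -> left-anterior
        -ys,                                           # C: anterior-posterior, occipital positive
        0.8 - (xs ** 2 + (ys - 0.2) ** 2),             # D: fronto-central maximum
    ])
    maps = _normalize_maps(maps)
    return {"channel_names": list(TEN_TWENTY_19), "templates": maps.tolist()}
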