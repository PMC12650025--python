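"""Statistical feature block: 40 descriptors in 26 categories, plus
Gini-importance feature selection.

The inventory covers time-domain moments, nonlinear/fractal descriptors,
spectral summaries and wavelet energies, computed per channel and
aggregated across channels (mean by default) into one named scalar per
feature.  Three information-theoretic descriptors — sample entropy, SVD
entropy and SVD-based Fisher information — are first-class citizens: they
are always retained by the selection step regardless of their importance
score.

Sample entropy here is the Richman-Moorman statistic

    SampEn(m, r) = -ln(A / B)

with ``A`` the number of template pairs matching at length ``m+1`` and
``B`` at length ``m`` under the Chebyshev distance (self-matches excluded).
Neighbour counting uses a k-d tree, which is exactly equivalent to the
O(n²) pairwise count (asserted against a brute-force oracle in the tests).

SVD entropy embeds the signal with order ``k`` and delay ``d``, normalises
the singular values to ``p_i = sigma_i / sum_j sigma_j`` and returns the
Shannon entropy ``-sum p_i ln p_i`` (bounded by ``ln k``).  The SVD Fisher
information measures local variation of the same spectrum:
``sum_{i>=2} (p_i - p_{i-1})^2 / (p_i + eps)`` with ``eps = 1e-8`` guarding
the division.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy.signal import welch
from scipy.spatial import cKDTree
from sklearn.ensemble import RandomForestClassifier

from .records import EEGRecord

__all__ = [
    "EntropyParams",
    "StatFeatureVector",
    "FeatureConfig",
    "sample_entropy",
    "app_entropy",
    "svd_entropy",
    "svd_fisher_info",
    "extract_channel_features",
    "extract_features",
    "gini_select",
    "SelectionResult",
    "INFO_THEORETIC_FEATURES",
    "FEATURE_NAMES",
]

EPS = 1e-8

#: Frequency bands (Hz) for relative power features.
POWER_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}
#: Bands for absolute energy features (4 entries keeps the manifest at 40).
ENERGY_BANDS = {k: POWER_BANDS[k] for k in ("delta", "theta", "alpha", "beta")}

INFO_THEORETIC_FEATURES = ("samp_entropy", "svd_entropy", "svd_fisher_info")

FEATURE_NAMES: tuple[str, ...] = (
    "std", "ptp", "skewness", "kurtosis", "rms",
    "quantile_q25", "quantile_q50", "quantile_q75",
    "hurst_exponent", "app_entropy", "samp_entropy", "decorr_time",
    *(f"pow_band_{b}" for b in POWER_BANDS),
    "hjorth_mobility_spect", "hjorth_complexity_spect",
    "hjorth_mobility", "hjorth_complexity",
    "higuchi_fd", "katz_fd", "zero_crossing_rate", "line_length",
    "spectral_slope", "spectral_entropy",
    "svd_entropy", "svd_fisher_info",
    *(f"energy_band_{b}" for b in ENERGY_BANDS),
    "spectral_edge_freq",
    *(f"wavelet_db4_energy_l{i}" for i in range(1, 7)),
)
assert len(FEATURE_NAMES) == 40


@dataclass
class EntropyParams:
    """Embedding parameters for the information-theoretic descriptors."""

    m: int = 2
    r: float = 0.2          # tolerance as a fraction of the signal SD
    svd_order: int = 3
    svd_delay: int = 1
    eps: float = EPS

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r <= 0:
            raise ValueError("r must be positive")
        if self.svd_order < 2:
            raise ValueError("svd_order must be >= 2")


@dataclass
class FeatureConfig:
    """Extraction settings; ``aggregate`` is mean | median | none."""

    aggregate: str = "mean"
    entropy: EntropyParams = field(default_factory=EntropyParams)
    wavelet_levels: int = 6
    higuchi_kmax: int = 10

    def __post_init__(self) -> None:
        if self.aggregate not in ("mean", "median", "none"):
            raise ValueError("aggregate must be mean|median|none")


@dataclass
class StatFeatureVector:
    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.names):
            raise ValueError("values/names length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite feature values")


# ---------------------------------------------------------------------------
# information-theoretic descriptors
# ---------------------------------------------------------------------------

def _embed(x: np.ndarray, order: int, delay: int) -> np.ndarray:
    n = len(x) - (order - 1) * delay
    if n < 1:
        raise ValueError(f"series too short for order={order}, delay={delay}")
    return np.stack([x[i * delay: i * delay + n] for i in range(order)], axis=1)


def _pair_count(templates: np.ndarray, r: float) -> int:
    """Unordered template pairs within Chebyshev distance r (self excluded)."""
    tree = cKDTree(templates)
    return tree.count_neighbors(tree, r, p=np.inf) - len(templates)  # ordered, minus self


def sample_entropy(x: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """Sample entropy ``-ln(A/B)`` with Chebyshev tolerance ``r * SD``.

    Self-matches are excluded.  Both counts use templates of the *same*
    population (the first ``N-m`` embeddings), the standard convention.
    Returns ``inf`` when no length-``m+1`` match exists (flagged no-match).
    """
    x = np.asarray(x, dtype=float)
    if len(x) <= m + 1:
        raise ValueError(f"series of length {len(x)} too short for m={m}")
    if r <= 0:
        raise ValueError("r must be positive")
    sd = x.std()
    if sd == 0:
        return 0.0  # every template matches at every length: A == B
    tol = r * sd
    n_templates = len(x) - m
    em = _embed(x, m, 1)[:n_templates]
    em1 = _embed(x, m + 1, 1)
    B = _pair_count(em, tol)
    A = _pair_count(em1, tol)
    if B == 0 or A == 0:
        return np.inf
    return -np.log(A / B)


def sample_entropy_cap(n: int, m: int = 2) -> float:
    """Upper bound ``-ln(2 / ((N-m-1)(N-m)))`` used to replace no-match runs."""
    return -np.log(2.0 / ((n - m - 1) * (n - m)))


def app_entropy(x: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """Approximate entropy ``phi(m) - phi(m+1)`` (self-matches included)."""
    x = np.asarray(x, dtype=float)
    if len(x) <= m + 1:
        raise ValueError("series too short")
    sd = x.std()
    if sd == 0:
        return 0.0
    tol = r * sd

    def phi(order: int) -> float:
        emb = _embed(x, order, 1)
        tree = cKDTree(emb)
        counts = tree.query_ball_point(emb, tol, p=np.inf, return_length=True)
        return float(np.mean(np.log(counts / len(emb))))

    return phi(m) - phi(m + 1)


def _svd_probs(x: np.ndarray, order: int, delay: int) -> np.ndarray:
    emb = _embed(np.asarray(x, dtype=float), order, delay)
    s = np.linalg.svd(emb, compute_uv=False)
    total = s.sum()
    if total == 0:
        return np.full(order, 1.0 / order)
    return s / total


def svd_entropy(x: np.ndarray, order: int = 3, delay: int = 1) -> float:
    """Shannon entropy of the normalised singular-value spectrum."""
    p = _svd_probs(x, order, delay)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def svd_fisher_info(
    x: np.ndarray | None,
    order: int = 3,
    delay: int = 1,
    eps: float = EPS,
    probs: np.ndarray | None = None,
) -> float:
    """Fisher information of the singular-value spectrum.

    ``probs`` is a test seam: when given, the spectrum is used directly
    instead of being computed from ``x``.
    """
    p = np.asarray(probs, dtype=float) if probs is not None else _svd_probs(x, order, delay)
    d = np.diff(p)
    return float((d ** 2 / (p[1:] + eps)).sum())


# ---------------------------------------------------------------------------
# remaining descriptors
# ---------------------------------------------------------------------------

def _hjorth_time(x: np.ndarray) -> tuple[float, float]:
    dx = np.diff(x)
    ddx = np.diff(dx)
    v0, v1, v2 = x.var(), dx.var(), ddx.var()
    mobility = np.sqrt(v1 / v0) if v0 > 0 else 0.0
    mob_d = np.sqrt(v2 / v1) if v1 > 0 else 0.0
    complexity = mob_d / mobility if mobility > 0 else 0.0
    return float(mobility), float(complexity)


def _hjorth_spectral(freqs: np.ndarray, psd: np.ndarray) -> tuple[float, float]:
    m0 = np.trapezoid(psd, freqs)
    m2 = np.trapezoid(psd * freqs ** 2, freqs)
    m4 = np.trapezoid(psd * freqs ** 4, freqs)
    if m0 <= 0 or m2 <= 0:
        return 0.0, 0.0
    mobility = np.sqrt(m2 / m0)
    complexity = np.sqrt(m4 / m2) / mobility
    return float(mobility), float(complexity)


def _hurst_rs(x: np.ndarray) -> float:
    """Rescaled-range Hurst exponent over dyadic segment sizes."""
    n = len(x)
    sizes = np.unique(np.floor(np.logspace(np.log10(10), np.log10(n // 2), 8)).astype(int))
    sizes = sizes[sizes >= 10]
    if len(sizes) < 2:
        return 0.5
    log_rs = []
    for s in sizes:
        n_seg = n // s
        segs = x[: n_seg * s].reshape(n_seg, s)
        segs = segs - segs.mean(axis=1, keepdims=True)
        z = np.cumsum(segs, axis=1)
        R = z.max(axis=1) - z.min(axis=1)
        S = segs.std(axis=1)
        ok = S > 0
        if not ok.any():
            return 0.5
        log_rs.append(np.log((R[ok] / S[ok]).mean()))
    slope = np.polyfit(np.log(sizes.astype(float)), np.array(log_rs), 1)[0]
    return float(slope)


def _higuchi_fd(x: np.ndarray, kmax: int) -> float:
    n = len(x)
    lk = []
    ks = []
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if len(idx) < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / (len(idx) - 1) / k
            lengths.append(dist * norm / k)
        if lengths:
            mean_l = np.mean(lengths)
            if mean_l > 0:
                lk.append(np.log(mean_l))
                ks.append(np.log(1.0 / k))
    if len(lk) < 2:
        return 1.0
    return float(np.polyfit(ks, lk, 1)[0])


def _katz_fd(x: np.ndarray) -> float:
    dists = np.abs(np.diff(x))
    L = dists.sum()
    if L == 0:
        return 1.0
    a = dists.mean()
    d = np.max(np.abs(x - x[0]))
    n = len(x) - 1
    if d == 0:
        return 1.0
    return float(np.log10(n) / (np.log10(n) + np.log10(d / L)))


def _decorrelation_time(x: np.ndarray, fs: float) -> float:
    xc = x - x.mean()
    v = (xc ** 2).sum()
    if v == 0:
        return 0.0
    acf = np.correlate(xc, xc, mode="full")[len(x) - 1:] / v
    below = np.nonzero(acf < 1.0 / np.e)[0]
    lag = int(below[0]) if len(below) else len(acf) - 1
    return lag / fs


def _band_mask(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    return (freqs >= band[0]) & (freqs < band[1])


def extract_channel_features(
    x: np.ndarray, fs: float, config: FeatureConfig | None = None
) -> dict[str, float]:
    """The 40-feature manifest for one channel."""
    cfg = config or FeatureConfig()
    x = np.asarray(x, dtype=float)
    n = len(x)
    ep = cfg.entropy
    out: dict[str, float] = {}

    out["std"] = float(x.std())
    out["ptp"] = float(np.ptp(x))
    sd = x.std()
    if sd > 0:
        z = (x - x.mean()) / sd
        out["skewness"] = float((z ** 3).mean())
        out["kurtosis"] = float((z ** 4).mean() - 3.0)
    else:
        out["skewness"] = 0.0
        out["kurtosis"] = 0.0
    out["rms"] = float(np.sqrt((x ** 2).mean()))
    q25, q50, q75 = np.quantile(x, [0.25, 0.5, 0.75])
    out["quantile_q25"], out["quantile_q50"], out["quantile_q75"] = map(float, (q25, q50, q75))

    out["hurst_exponent"] = _hurst_rs(x) if sd > 0 else 0.5
    out["app_entropy"] = app_entropy(x, ep.m, ep.r)
    se = sample_entropy(x, ep.m, ep.r)
    out["samp_entropy"] = se if np.isfinite(se) else sample_entropy_cap(n, ep.m)
    out["decorr_time"] = _decorrelation_time(x, fs)

    nperseg = min(256, n)
    freqs, psd = welch(x, fs=fs, nperseg=nperseg)
    total_power = np.trapezoid(psd, freqs)
    for band, (lo, hi) in POWER_BANDS.items():
        mask = _band_mask(freqs, (lo, hi))
        p = np.trapezoid(psd[mask], freqs[mask]) if mask.sum() > 1 else 0.0
        out[f"pow_band_{band}"] = float(p / total_power) if total_power > 0 else 0.0

    mob_s, comp_s = _hjorth_spectral(freqs, psd)
    out["hjorth_mobility_spect"] = mob_s
    out["hjorth_complexity_spect"] = comp_s
    out["hjorth_mobility"], out["hjorth_complexity"] = _hjorth_time(x)

    out["higuchi_fd"] = _higuchi_fd(x, cfg.higuchi_kmax) if sd > 0 else 1.0
    out["katz_fd"] = _katz_fd(x)
    xm = x - x.mean()
    out["zero_crossing_rate"] = float(np.sum(np.diff(np.signbit(xm)) != 0) / (n / fs))
    out["line_length"] = float(np.abs(np.diff(x)).mean()) if n > 1 else 0.0

    fit_mask = (freqs >= 1.0) & (freqs <= 45.0) & (psd > 0)
    if fit_mask.sum() >= 2:
        out["spectral_slope"] = float(
            np.polyfit(np.log10(freqs[fit_mask]), np.log10(psd[fit_mask]), 1)[0]
        )
    else:
        out["spectral_slope"] = 0.0
    p_norm = psd / psd.sum() if psd.sum() > 0 else None
    if p_norm is not None:
        nz = p_norm[p_norm > 0]
        out["spectral_entropy"] = float(-(nz * np.log(nz)).sum() / np.log(len(p_norm)))
    else:
        out["spectral_entropy"] = 0.0

    out["svd_entropy"] = svd_entropy(x, ep.svd_order, ep.svd_delay)
    out["svd_fisher_info"] = svd_fisher_info(x, ep.svd_order, ep.svd_delay, ep.eps)

    for band, (lo, hi) in ENERGY_BANDS.items():
        mask = _band_mask(freqs, (lo, hi))
        e = np.trapezoid(psd[mask], freqs[mask]) if mask.sum() > 1 else 0.0
        out[f"energy_band_{band}"] = float(np.log1p(e * n))

    if total_power > 0:
        cum = np.cumsum(psd) / psd.sum()
        out["spectral_edge_freq"] = float(freqs[np.searchsorted(cum, 0.95)])
    else:
        out["spectral_edge_freq"] = 0.0

    coeffs = pywt.wavedec(x, "db4", level=cfg.wavelet_levels)
    energies = np.array([(c ** 2).sum() for c in coeffs[1:]])  # detail levels 1..L (fine→coarse order reversed)
    total_e = energies.sum()
    rel = energies / total_e if total_e > 0 else np.zeros_like(energies)
    # coeffs[1:] are ordered coarse→fine; level 1 = finest detail
    for i, r in enumerate(reversed(rel), start=1):
        out[f"wavelet_db4_energy_l{i}"] = float(r)

    assert list(out.keys()) == list(FEATURE_NAMES)
    return out


def _min_length_violations(n: int, cfg: FeatureConfig) -> list[str]:
    bad = []
    ep = cfg.entropy
    if n <= ep.m + 1:
        bad += ["samp_entropy", "app_entropy"]
    if n < ep.svd_order * ep.svd_delay + 1:
        bad += ["svd_entropy", "svd_fisher_info"]
    if pywt.dwt_max_level(n, pywt.Wavelet("db4").dec_len) < cfg.wavelet_levels:
        bad += [f"wavelet_db4_energy_l{i}" for i in range(1, cfg.wavelet_levels + 1)]
    if n < 20:
        bad += ["hurst_exponent"]
    return bad


def extract_features(
    rec: EEGRecord, config: FeatureConfig | None = None
) -> StatFeatureVector:
    """Per-channel manifest aggregated across channels.

    Aggregation is the cross-channel mean by default (``median`` and
    ``none`` are available; ``none`` yields channel-suffixed names).
    Raises when the record is too short for some features, listing them.
    """
    cfg = config or FeatureConfig()
    bad = _min_length_violations(rec.n_samples, cfg)
    if bad:
        raise ValueError(
            f"record too short ({rec.n_samples} samples) for features: {sorted(set(bad))}"
        )
    per_channel = np.array(
        [list(extract_channel_features(ch, rec.fs_hz, cfg).values()) for ch in rec.data]
    )  # (n_ch, 40)
    if cfg.aggregate == "mean":
        return StatFeatureVector(per_channel.mean(axis=0), list(FEATURE_NAMES))
    if cfg.aggregate == "median":
        return StatFeatureVector(np.median(per_channel, axis=0), list(FEATURE_NAMES))
    names = [f"{f}__{ch}" for ch in rec.channel_names for f in FEATURE_NAMES]
    return StatFeatureVector(per_channel.ravel(), names)


# ---------------------------------------------------------------------------
# Gini-importance selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    names: list[str]
    mask: np.ndarray
    importances: np.ndarray


def gini_select(
    feature_matrix: np.ndarray,
    labels: np.ndarray,
    feature_names: list[str],
    threshold: float = 0.002,
    seed: int = 0,
    always_keep: tuple[str, ...] = INFO_THEORETIC_FEATURES,
    n_estimators: int = 300,
) -> SelectionResult:
    """Drop features whose random-forest Gini importance falls below
    ``threshold``; the information-theoretic features are always retained.

    Impurity-based importances sum to 1, so the threshold is a share of the
    total impurity reduction.  Meant to be fitted on training folds only.
    """
    X = np.asarray(feature_matrix, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 samples for importance estimation")
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain at least 2 classes")
    if X.shape[1] != len(feature_names):
        raise ValueError("feature_names length mismatch")
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    imp = rf.feature_importances_
    mask = imp >= threshold
    for nm in always_keep:
        for i, name in enumerate(feature_names):
            if name == nm or name.startswith(nm + "__"):
                mask[i] = True
    kept = [n for n, m in zip(feature_names, mask) if m]
    return SelectionResult(names=kept, mask=mask, importances=imp)
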