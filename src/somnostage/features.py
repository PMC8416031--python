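"""Per-epoch feature extraction: 152 features per channel per 30-s epoch.

From each channel-epoch ten sequences are built: the raw samples, their first
difference, and eight spectral-band sequences — the Welch PSD bin values and
the Lomb-Scargle PSD bin values restricted to the delta (0.5-4 Hz), theta
(4-8 Hz), alpha (8-13 Hz) and beta (13-30 Hz) bands. Fourteen descriptive
statistics of each sequence give 140 features; twelve non-linear features
complete the 152:

* permutation, sample and SVD entropy of the raw sequence (3),
* the same three entropies of the first difference (3),
* absolute Welch band energies in delta/theta/alpha/beta (4),
* spectral Shannon entropy of the Welch PSD and of the Lomb PSD (2).

The fourteen statistics, in fixed order: max, min, mean, var (population),
std, 25th/75th/95th percentile, skewness, excess kurtosis, median,
zero-crossing rate, Hjorth mobility, Hjorth complexity. Degenerate inputs
(constant sequences, zero denominators) map to 0 by convention so a feature
matrix never contains NaN or Inf.

Six channels in the canonical order C4, EMG, LEOG, REOG, F4, O2 give 912
features per epoch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.preprocessing import StandardScaler

from ._entropy import sampen_counts

__all__ = [
    "BANDS",
    "CANONICAL_CHANNEL_ORDER",
    "FEATURES_PER_CHANNEL",
    "SequenceBank",
    "FeatureMatrix",
    "NormalizationParams",
    "build_sequence_bank",
    "descriptive_stats",
    "band_energy",
    "permutation_entropy",
    "sample_entropy",
    "svd_entropy",
    "spectral_entropy",
    "extract_channel_features",
    "channel_feature_names",
    "extract_features",
    "fit_normalizer",
    "apply_normalizer",
    "EpochFeatureExtractor",
]

BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

CANONICAL_CHANNEL_ORDER = ("C4", "EMG", "LEOG", "REOG", "F4", "O2")

STAT_NAMES = (
    "max",
    "min",
    "mean",
    "var",
    "std",
    "per25",
    "per75",
    "per95",
    "skew",
    "kurt",
    "median",
    "overzero",
    "hjorth_mobility",
    "hjorth_complexity",
)

SEQUENCE_NAMES = (
    "raw",
    "diff1",
    "welch_delta",
    "welch_theta",
    "welch_alpha",
    "welch_beta",
    "lomb_delta",
    "lomb_theta",
    "lomb_alpha",
    "lomb_beta",
)

NONLINEAR_NAMES = (
    "permEn_raw",
    "sampEn_raw",
    "svdEn_raw",
    "permEn_diff1",
    "sampEn_diff1",
    "svdEn_diff1",
    "energy_delta",
    "energy_theta",
    "energy_alpha",
    "energy_beta",
    "specEn_welch",
    "specEn_lomb",
)

FEATURES_PER_CHANNEL = len(SEQUENCE_NAMES) * len(STAT_NAMES) + len(NONLINEAR_NAMES)

# Sample entropy runs on the epoch decimated by this stride: the quadratic
# template search dominates extraction cost and the decimated value preserves
# the stage ordering of the statistic.
SAMPEN_STRIDE = 3

_LOMB_DF = 0.25


@dataclass
class SequenceBank:
    """The ten per-channel-epoch sequences plus full PSDs for energy features."""

    sequences: dict[str, np.ndarray]
    welch_freqs: np.ndarray
    welch_psd: np.ndarray
    lomb_freqs: np.ndarray
    lomb_psd: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        if set(self.sequences) != set(SEQUENCE_NAMES):
            raise ValueError("sequence bank must contain exactly the 10 named sequences")
        for name in SEQUENCE_NAMES[2:]:
            if np.any(self.sequences[name] < 0):
                raise ValueError(f"band sequence {name} contains negative PSD values")


@dataclass
class FeatureMatrix:
    """T epochs x F features with provenance."""

    values: np.ndarray
    feature_names: list[str]
    channel_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D (epochs x features)")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match feature count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains NaN/Inf")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def canonical_channel_sort(labels) -> list[str]:
    """Order labels C4, EMG, LEOG, REOG, F4, O2 first; unknown labels keep
    their given relative order after the canonical ones."""
    labels = list(labels)
    rank = {c: i for i, c in enumerate(CANONICAL_CHANNEL_ORDER)}
    return sorted(labels, key=lambda c: (rank.get(c, len(rank)), labels.index(c)))


def _band_mask(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    low, high = band
    return (freqs >= low) & (freqs < high)


# Lomb-Scargle on a uniform time base: the per-frequency trig factors
# cos/sin(w (t - tau)) and their squared sums do not depend on the data, so
# they are precomputed once per (n_samples, rate) and each call reduces to two
# matrix-vector products. Verified against scipy.signal.lombscargle in tests.
_LOMB_CACHE: dict[tuple[int, float], tuple] = {}


def _lomb_tables(n: int, rate: float):
    key = (n, float(rate))
    if key not in _LOMB_CACHE:
        nyq = rate / 2.0
        freqs = np.arange(0.5, min(30.0, 0.99 * nyq) + _LOMB_DF / 2, _LOMB_DF)
        t = np.arange(n) / rate
        w = 2 * np.pi * freqs
        wt = w[:, None] * t[None, :]
        tau = np.arctan2(np.sin(2 * wt).sum(axis=1), np.cos(2 * wt).sum(axis=1)) / (
            2 * w
        )
        arg = wt - (w * tau)[:, None]
        C = np.cos(arg)
        S = np.sin(arg)
        cc = (C**2).sum(axis=1)
        ss = (S**2).sum(axis=1)
        _LOMB_CACHE[key] = (freqs, C, S, cc, ss)
    return _LOMB_CACHE[key]


def _lomb_psd(x: np.ndarray, rate: float):
    freqs, C, S, cc, ss = _lomb_tables(x.size, rate)
    xc = x - x.mean()
    if not np.any(xc):
        return freqs, np.zeros_like(freqs)
    xC = C @ xc
    xS = S @ xc
    with np.errstate(divide="ignore", invalid="ignore"):
        psd = 0.5 * (np.where(cc > 0, xC**2 / cc, 0.0) + np.where(ss > 0, xS**2 / ss, 0.0))
    return freqs, psd


def build_sequence_bank(epoch, rate: float) -> SequenceBank:
    """Build the ten sequences for one channel-epoch."""
    x = np.asarray(epoch, dtype=float).ravel()
    nyq = rate / 2.0
    if nyq <= BANDS["beta"][1]:
        raise ValueError(
            f"sampling rate {rate} Hz too low for the beta band (needs Nyquist > 30 Hz)"
        )
    nperseg = min(256, x.size)
    f_w, psd_w = sps.welch(
        x, fs=rate, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )

    f_l, psd_l = _lomb_psd(x, rate)

    sequences = {"raw": x, "diff1": np.diff(x)}
    for band, rng in BANDS.items():
        sequences[f"welch_{band}"] = psd_w[_band_mask(f_w, rng)]
        sequences[f"lomb_{band}"] = psd_l[_band_mask(f_l, rng)]
    return SequenceBank(
        sequences=sequences,
        welch_freqs=f_w,
        welch_psd=psd_w,
        lomb_freqs=f_l,
        lomb_psd=psd_l,
        rate=rate,
    )


def descriptive_stats(seq) -> np.ndarray:
    """The 14 descriptive statistics of one sequence, in fixed order."""
    x = np.asarray(seq, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("descriptive statistics need at least 3 samples")
    mean = float(x.mean())
    xc = x - mean
    x2 = xc * xc
    var = float(x2.mean())  # population convention
    # round-off floor: a constant vector must come out exactly degenerate
    if var <= (1e-12 * max(abs(float(x.max())), abs(float(x.min())), 1e-300)) ** 2:
        var = 0.0
    std = math.sqrt(var)
    if var > 0:
        skew = float((x2 * xc).mean()) / var**1.5
        kurt = float((x2 * x2).mean()) / var**2 - 3.0  # Fisher (excess)
    else:
        skew = 0.0
        kurt = 0.0
    zcr = float(np.count_nonzero(x[:-1] * x[1:] < 0)) / (x.size - 1)

    d1 = np.diff(x)
    var_d1 = float(np.var(d1))
    mobility = math.sqrt(var_d1 / var) if var > 0 else 0.0
    d2 = np.diff(d1)
    var_d2 = float(np.var(d2))
    mob_d1 = math.sqrt(var_d2 / var_d1) if var_d1 > 0 else 0.0
    complexity = mob_d1 / mobility if mobility > 0 else 0.0

    q25, median, q75, q95 = np.percentile(x, [25, 50, 75, 95])
    return np.array(
        [
            float(x.max()),
            float(x.min()),
            mean,
            var,
            std,
            float(q25),
            float(q75),
            float(q95),
            skew,
            kurt,
            float(median),
            zcr,
            mobility,
            complexity,
        ]
    )


def band_energy(bank: SequenceBank) -> np.ndarray:
    """Absolute integrated Welch power in delta, theta, alpha, beta."""
    energies = []
    for band, rng in BANDS.items():
        mask = _band_mask(bank.welch_freqs, rng)
        energies.append(float(np.trapezoid(bank.welch_psd[mask], bank.welch_freqs[mask])))
    return np.array(energies)


def permutation_entropy(seq, order: int = 3, delay: int = 1) -> float:
    """Normalized Shannon entropy of ordinal patterns, in [0, 1].

    Ties are broken earlier-index-smaller (stable sort).
    """
    x = np.asarray(seq, dtype=float).ravel()
    n_win = x.size - (order - 1) * delay
    if n_win < 1:
        raise ValueError("sequence too short for the requested order/delay")
    idx = np.arange(n_win)[:, None] + np.arange(order)[None, :] * delay
    patterns = np.argsort(x[idx], axis=1, kind="stable")
    codes = (patterns * (order ** np.arange(order))[None, :]).sum(axis=1)
    counts = np.bincount(codes)
    p = counts[counts > 0] / n_win
    return float(-(p * np.log(p)).sum() / math.log(math.factorial(order)))


def sample_entropy(seq, m: int = 2, r: float = 0.2) -> float:
    """Sample entropy -ln(A/B), Chebyshev distance, self-matches excluded.

    ``r`` is a multiple of the sequence standard deviation. When no template
    pair matches at length m or m+1 the statistic is undefined; the documented
    cap ln(n_pairs) (log of the template-pair count bound) is returned
    instead of infinity.
    """
    x = np.ascontiguousarray(seq, dtype=np.float64).ravel()
    if x.size < m + 2:
        raise ValueError("sequence too short for sample entropy")
    tol = r * float(np.std(x))
    A, B = sampen_counts(x, m, tol)
    nt = x.size - m
    cap = math.log(nt * (nt - 1) / 2.0)
    if B == 0 or A == 0:
        return cap
    return float(-math.log(A / B))


def svd_entropy(seq, embed_dim: int = 10, delay: int = 1) -> float:
    """Normalized Shannon entropy of the delay-embedding singular values."""
    x = np.asarray(seq, dtype=float).ravel()
    n_rows = x.size - (embed_dim - 1) * delay
    if n_rows < 1:
        raise ValueError("sequence too short for the requested embedding")
    idx = np.arange(n_rows)[:, None] + np.arange(embed_dim)[None, :] * delay
    Y = x[idx]
    # Singular values via the small Gram matrix (embed_dim x embed_dim).
    ev = np.linalg.eigvalsh(Y.T @ Y)
    s = np.sqrt(np.clip(ev, 0.0, None))
    total = s.sum()
    if total == 0.0:
        return 0.0
    p = s[s > 0] / total
    return float(-(p * np.log(p)).sum() / math.log(embed_dim))


def spectral_entropy(psd: np.ndarray) -> float:
    """Normalized Shannon entropy of a PSD treated as a distribution over bins."""
    psd = np.asarray(psd, dtype=float).ravel()
    total = psd.sum()
    if total <= 0 or psd.size < 2:
        return 0.0
    p = psd[psd > 0] / total
    return float(-(p * np.log(p)).sum() / math.log(psd.size))


def extract_channel_features(epoch, rate: float) -> np.ndarray:
    """The 152-dimensional feature vector of one channel-epoch."""
    bank = build_sequence_bank(epoch, rate)
    feats = np.empty(FEATURES_PER_CHANNEL)
    pos = 0
    for name in SEQUENCE_NAMES:
        feats[pos : pos + 14] = descriptive_stats(bank.sequences[name])
        pos += 14

    raw = bank.sequences["raw"]
    diff1 = bank.sequences["diff1"]
    raw_s = raw[::SAMPEN_STRIDE]
    diff1_s = diff1[::SAMPEN_STRIDE]
    nonlinear = [
        permutation_entropy(raw),
        sample_entropy(raw_s),
        svd_entropy(raw),
        permutation_entropy(diff1),
        sample_entropy(diff1_s),
        svd_entropy(diff1),
        *band_energy(bank),
        spectral_entropy(bank.welch_psd),
        spectral_entropy(bank.lomb_psd),
    ]
    feats[pos:] = nonlinear
    if not np.all(np.isfinite(feats)):
        raise FloatingPointError("non-finite feature encountered")
    return feats


def channel_feature_names(channel: str) -> list[str]:
    names = [
        f"{channel}|{seq}|{stat}" for seq in SEQUENCE_NAMES for stat in STAT_NAMES
    ]
    names += [f"{channel}|{nl}" for nl in NONLINEAR_NAMES]
    return names


def extract_features(data: np.ndarray, channel_labels, rate: float) -> FeatureMatrix:
    """Feature matrix for an epoched night.

    Parameters
    ----------
    data : (T, C, S) array
        Epoched signal, microvolts; S = 30 * rate samples per epoch.
    channel_labels : list of str
        Labels for the C channels of ``data``. Output channel blocks follow
        the canonical order C4, EMG, LEOG, REOG, F4, O2 regardless of the
        input order.
    rate : float
        Sampling rate in Hz.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("epoched data must be (T, C, S)")
    labels = list(channel_labels)
    if len(labels) != data.shape[1]:
        raise ValueError("channel label count must match data")
    ordered = canonical_channel_sort(labels)
    T = data.shape[0]
    values = np.empty((T, FEATURES_PER_CHANNEL * len(ordered)))
    names: list[str] = []
    for ci, ch in enumerate(ordered):
        src = labels.index(ch)
        block = slice(ci * FEATURES_PER_CHANNEL, (ci + 1) * FEATURES_PER_CHANNEL)
        for t in range(T):
            values[t, block] = extract_channel_features(data[t, src], rate)
        names.extend(channel_feature_names(ch))
    return FeatureMatrix(values=values, feature_names=names, channel_order=ordered)


@dataclass
class NormalizationParams:
    """Per-feature z-scoring parameters estimated on training data."""

    mean: np.ndarray
    std: np.ndarray
    epsilon: float = 1e-8


def fit_normalizer(train: FeatureMatrix | np.ndarray, epsilon: float = 1e-8) -> NormalizationParams:
    """Fit per-feature mean/std (population) on training rows only."""
    X = train.values if isinstance(train, FeatureMatrix) else np.asarray(train, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("normalizer needs at least 2 training rows")
    scaler = StandardScaler().fit(X)
    std = np.sqrt(scaler.var_)
    return NormalizationParams(mean=scaler.mean_, std=std, epsilon=epsilon)


def apply_normalizer(fm: FeatureMatrix | np.ndarray, params: NormalizationParams):
    """z-score features; features with training std below epsilon map to 0."""
    is_fm = isinstance(fm, FeatureMatrix)
    X = fm.values if is_fm else np.asarray(fm, dtype=float)
    degenerate = params.std < params.epsilon
    denom = np.where(degenerate, 1.0, params.std)
    Z = (X - params.mean) / denom
    Z[:, degenerate] = 0.0
    if is_fm:
        return FeatureMatrix(values=Z, feature_names=list(fm.feature_names),
                             channel_order=list(fm.channel_order))
    return Z


class EpochFeatureExtractor(TransformerMixin, BaseEstimator):
    """scikit-learn transformer view of the per-epoch feature extractor.

    ``transform`` maps an epoched night of shape (T, C, S) to the (T, F)
    feature matrix, F = 152 per channel. Stateless apart from parameters.
    """

    def __init__(self, channel_labels=None, rate: float = 100.0):
        self.channel_labels = channel_labels
        self.rate = rate

    def fit(self, X=None, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        labels = self.channel_labels
        if labels is None:
            labels = [f"ch{i}" for i in range(np.asarray(X).shape[1])]
        return extract_features(X, labels, self.rate).values
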