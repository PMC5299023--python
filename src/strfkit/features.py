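"""Spectro-temporal feature extraction and a thin classification harness.

STRF or Gabor patches act as 2D filters on Bark spectrograms (one output
channel per spectral alignment, 21 per filter), optionally thinned by
width-based channel subsampling and decorrelated by PCA.  An MFCC
front-end (13 cepstra + delta + double-delta = 39 dims per 10 ms frame)
serves as the purely spectral baseline.  A synthetic event corpus with
SNR-controlled noise mixing and an RBF-SVM one-vs-all harness close the
classification loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import fft as sfft
from scipy import signal
from sklearn.decomposition import PCA
from sklearn.model_selection import GridSearchCV
from sklearn.multiclass import OneVsRestClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .gabor import GaborAtom, hann_envelope
from .periphery import BarkSpectrogram

__all__ = [
    "FeatureMatrix",
    "CorpusSpec",
    "EventCorpus",
    "ClassifierConfig",
    "ClassificationReport",
    "filter_features",
    "spectral_width",
    "subsample_channels",
    "pca_decorrelate",
    "mfcc_features",
    "synth_event_corpus",
    "mix_at_snr",
    "event_vector",
    "classify",
]


@dataclass
class FeatureMatrix:
    """Frame-wise feature values with per-column provenance labels."""

    values: np.ndarray = field(repr=False)
    dim_labels: list = field(repr=False)
    frame_period_ms: float = 2.0

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_dims(self) -> int:
        return self.values.shape[1]

    def __post_init__(self):
        if len(self.dim_labels) != self.values.shape[1]:
            raise ValueError("one label per feature column required")
        if len(set(self.dim_labels)) != len(self.dim_labels):
            raise ValueError("dim_labels must be unique")

    def decimate(self, factor: int) -> "FeatureMatrix":
        """Mean-pool frames by an integer factor (temporal resampling)."""
        n = (self.n_frames // factor) * factor
        pooled = self.values[:n].reshape(-1, factor, self.n_dims).mean(axis=1)
        return FeatureMatrix(pooled, self.dim_labels,
                             self.frame_period_ms * factor)


def filter_features(spec: BarkSpectrogram, filters,
                    channel_subsets=None) -> FeatureMatrix:
    """2D-filter a spectrogram with a list of STRF/Gabor patches.

    Each filter is correlated with the spectrogram in 'same' mode along
    both axes (zero-padding in time, edge clipping across channels), so
    every filter contributes one output per spectral alignment — 21
    channels per filter at the default periphery.  Complex filters
    contribute their real part.  ``channel_subsets`` optionally maps
    filter index -> retained channel indices (see
    :func:`subsample_channels`).

    Returns
    -------
    FeatureMatrix
        frames x (sum of retained channels) with (filter_id, channel)
        labels.
    """
    X = np.asarray(spec.values, dtype=float)
    n_ch = X.shape[0]
    cols, labels = [], []
    for fid, filt in enumerate(filters):
        patch = filt.patch if isinstance(filt, GaborAtom) else np.asarray(filt)
        patch = np.real(patch).astype(float)
        if patch.shape[0] > n_ch:
            raise ValueError(
                f"filter {fid} has {patch.shape[0]} channels > spectrogram's {n_ch}")
        out = signal.fftconvolve(X, np.flip(patch), mode="same")
        keep = (range(n_ch) if channel_subsets is None
                else channel_subsets[fid])
        for c in keep:
            cols.append(out[c])
            labels.append((fid, int(c)))
    return FeatureMatrix(np.asarray(cols).T, labels, spec.frame_period_ms)


def spectral_width(filter_patch, kind: str) -> float:
    """Spectral width of a 2D filter, in channels.

    kind="gabor": width of the spectral envelope at its 1/e decay point.
    For a :class:`GaborAtom` this is closed-form from the Hann envelope
    width b_s (``b_s * arccos(2/e - 1) / pi``); for a bare patch the
    envelope is taken as the root-sum-square spectral profile and the 1/e
    crossings are located by linear interpolation.

    kind="strf": length of the smallest contiguous channel span around
    the energy centroid holding >= 90% of the squared-coefficient energy.
    """
    if kind not in ("gabor", "strf"):
        raise ValueError("kind must be 'gabor' or 'strf'")
    if isinstance(filter_patch, GaborAtom):
        if kind != "gabor":
            raise ValueError("GaborAtom width uses kind='gabor'")
        return filter_patch.b_s * math.acos(2.0 / math.e - 1.0) / math.pi

    patch = np.asarray(filter_patch)
    if not np.any(patch):
        raise ValueError("zero patch has no spectral width")
    energy = np.sum(np.abs(patch) ** 2, axis=1)

    if kind == "gabor":
        profile = np.sqrt(energy)
        peak = profile.max()
        level = peak / math.e
        above = np.flatnonzero(profile >= level)
        lo, hi = above[0], above[-1]

        def _cross(i_out, i_in):
            p0, p1 = profile[i_out], profile[i_in]
            if p1 == p0:
                return float(i_in)
            return i_out + (level - p0) / (p1 - p0) * (i_in - i_out)

        left = _cross(lo - 1, lo) if lo > 0 else float(lo)
        right = _cross(hi + 1, hi) if hi < profile.size - 1 else float(hi)
        return right - left

    total = energy.sum()
    centroid = float(np.sum(np.arange(energy.size) * energy) / total)
    lo = hi = int(math.floor(centroid + 0.5))
    lo = hi = min(max(lo, 0), energy.size - 1)
    covered = energy[lo]
    while covered < 0.9 * total:
        left = energy[lo - 1] if lo > 0 else -np.inf
        right = energy[hi + 1] if hi < energy.size - 1 else -np.inf
        if left >= right:  # tie toward lower channels
            lo -= 1
            covered += energy[lo]
        else:
            hi += 1
            covered += energy[hi]
    return float(hi - lo + 1)


def subsample_channels(n_channels: int, width: float) -> np.ndarray:
    """Greedy channel thinning: drop channels closer than width/4.

    Scans bottom-up from the first channel, keeping a channel iff its
    distance to the last kept channel is at least ``width / 4``; the
    first channel is always kept.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    kept = [0]
    for c in range(1, n_channels):
        if c - kept[-1] >= width / 4.0:
            kept.append(c)
    return np.asarray(kept)


def pca_decorrelate(train, test=None, variance_target: float = 0.99):
    """Decorrelate features with a rotation fit on the training set only.

    Returns
    -------
    (train_t, test_t, curve, n_components)
        Projections onto the leading components reaching
        ``variance_target`` cumulative explained variance, the full
        cumulative-variance curve, and the component count.  ``test_t``
        is None when no test matrix is given.
    """
    if not 0.0 < variance_target <= 1.0:
        raise ValueError("variance_target must be in (0, 1]")
    Xtr = train.values if isinstance(train, FeatureMatrix) else np.asarray(train)
    if Xtr.shape[0] < 2:
        raise ValueError("need at least 2 training rows for PCA")
    pca = PCA()
    pca.fit(Xtr)
    curve = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(curve, variance_target - 1e-12) + 1)
    n_comp = min(n_comp, curve.size)
    train_t = pca.transform(Xtr)[:, :n_comp]
    test_t = None
    if test is not None:
        Xte = test.values if isinstance(test, FeatureMatrix) else np.asarray(test)
        test_t = pca.transform(Xte)[:, :n_comp]
    return train_t, test_t, curve, n_comp


# ---------------------------------------------------------------------------
# MFCC baseline (HTK-style dialect, frozen here)

def _mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_inv(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def _mel_filterbank(n_filters, n_fft, sample_rate):
    edges = _mel_inv(np.linspace(_mel(0.0), _mel(sample_rate / 2.0), n_filters + 2))
    bins = np.fft.rfftfreq(n_fft, 1.0 / sample_rate)
    fb = np.zeros((n_filters, bins.size))
    for i in range(n_filters):
        lo, c, hi = edges[i], edges[i + 1], edges[i + 2]
        up = (bins - lo) / (c - lo)
        down = (hi - bins) / (hi - c)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def _slope(x: np.ndarray, half: int) -> np.ndarray:
    """Linear-regression slope over a (2*half+1)-point window, per column,
    with edge replication."""
    k = np.arange(1, half + 1, dtype=float)
    denom = 2.0 * np.sum(k ** 2)
    padded = np.pad(x, ((half, half), (0, 0)), mode="edge")
    out = np.zeros_like(x)
    for j, kk in enumerate(k, start=1):
        out += kk * (padded[half + j : half + j + x.shape[0]]
                     - padded[half - j : half - j + x.shape[0]])
    return out / denom


def mfcc_features(audio, sample_rate: int = 16000) -> FeatureMatrix:
    """39-dimensional MFCC features at a 10 ms frame period.

    25 ms periodic-Hann frames, 10 ms hop, 512-point power spectrum, 23
    triangular mel filters over 0-8 kHz, log compression, orthonormal
    DCT-II; 13 cepstra with c0 replaced by the log frame energy, plus
    delta (7-point linear slope) and double-delta (9-point slope of the
    deltas).
    """
    x = np.asarray(audio, dtype=float)
    if x.ndim != 1:
        raise ValueError("audio must be mono")
    frame_len = int(round(0.025 * sample_rate))
    hop = int(round(0.010 * sample_rate))
    if x.size < frame_len:
        raise ValueError("audio shorter than one MFCC frame")
    n_fft = 512
    n_frames = (x.size - frame_len) // hop + 1
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx]
    log_energy = np.log(np.maximum(np.sum(frames ** 2, axis=1), 1e-12))
    win = signal.get_window("hann", frame_len, fftbins=True)
    power = np.abs(np.fft.rfft(frames * win, n=n_fft, axis=1)) ** 2
    fb = _mel_filterbank(23, n_fft, sample_rate)
    logmel = np.log(np.maximum(power @ fb.T, 1e-12))
    cep = sfft.dct(logmel, type=2, norm="ortho", axis=1)[:, :13]
    cep[:, 0] = log_energy
    delta = _slope(cep, 3)
    ddelta = _slope(delta, 4)
    values = np.hstack([cep, delta, ddelta])
    labels = ([("mfcc", i) for i in range(13)]
              + [("delta", i) for i in range(13)]
              + [("ddelta", i) for i in range(13)])
    return FeatureMatrix(values, labels, frame_period_ms=10.0)


# ---------------------------------------------------------------------------
# Synthetic event corpus

def _tone_complex(rng, n, sr):
    f0 = rng.uniform(300.0, 900.0)
    t = np.arange(n) / sr
    x = sum(rng.uniform(0.3, 1.0) * np.sin(2 * np.pi * f0 * (k + 1) * t
                                           + rng.uniform(0, 2 * np.pi))
            for k in range(4))
    return x


def _click_train(rng, n, sr):
    rate = rng.uniform(15.0, 40.0)
    period = int(sr / rate)
    x = np.zeros(n)
    width = int(0.002 * sr)
    for start in range(rng.integers(0, period), n - width, period):
        x[start:start + width] += np.hanning(width)
    return x


def _noise_burst(rng, n, sr):
    x = rng.standard_normal(n)
    env = np.zeros(n)
    pos = 0
    while pos < n:
        dur = int(rng.uniform(0.05, 0.12) * sr)
        env[pos:pos + dur] = np.hanning(min(dur, n - pos))[: max(0, min(dur, n - pos))]
        pos += dur + int(rng.uniform(0.05, 0.1) * sr)
    b, a = signal.butter(4, [rng.uniform(0.1, 0.2), rng.uniform(0.5, 0.8)], "band")
    return signal.lfilter(b, a, x * env)


def _am_tone(rng, n, sr):
    t = np.arange(n) / sr
    fc = rng.uniform(800.0, 2000.0)
    fm = rng.uniform(8.0, 30.0)
    return (1.0 + 0.9 * np.sin(2 * np.pi * fm * t)) * np.sin(
        2 * np.pi * fc * t + rng.uniform(0, 2 * np.pi))


def _fm_sweep(rng, n, sr):
    t = np.arange(n) / sr
    f0 = rng.uniform(300.0, 800.0)
    f1 = rng.uniform(2000.0, 6000.0)
    reps = max(1, int(t[-1] / rng.uniform(0.15, 0.3)))
    seg = n // reps
    x = np.zeros(n)
    for i in range(reps):
        tt = t[:seg]
        x[i * seg:(i + 1) * seg] = signal.chirp(tt, f0, tt[-1], f1)
    return x


def _modulated_noise(rng, n, sr):
    x = rng.standard_normal(n)
    b, a = signal.butter(4, rng.uniform(0.3, 0.6))
    x = signal.lfilter(b, a, x)
    t = np.arange(n) / sr
    fm = rng.uniform(3.0, 10.0)
    return x * (1.0 + 0.8 * np.sin(2 * np.pi * fm * t))


_CLASS_GENERATORS = {
    "tone_complex": _tone_complex,
    "click_train": _click_train,
    "noise_burst": _noise_burst,
    "am_tone": _am_tone,
    "fm_sweep": _fm_sweep,
    "modulated_noise": _modulated_noise,
}


@dataclass
class CorpusSpec:
    """Synthetic-event corpus specification.

    Six default classes with distinct modulation signatures emulate an
    everyday-sound event set; noise mixing at stated SNRs uses stationary
    Gaussian or amplitude-modulated Gaussian noise.
    """

    classes: tuple = tuple(_CLASS_GENERATORS)
    n_train: int = 20
    n_test: int = 10
    snr_list: tuple = ()
    noise_kind: str = "stationary"
    duration_s: float = 0.5
    sample_rate: int = 16000
    seed: int | None = None

    def __post_init__(self):
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")
        unknown = set(self.classes) - set(_CLASS_GENERATORS)
        if unknown:
            raise ValueError(f"unknown class generators: {sorted(unknown)}")
        if self.noise_kind not in ("stationary", "modulated"):
            raise ValueError("noise_kind must be 'stationary' or 'modulated'")


@dataclass
class EventCorpus:
    """Labelled waveforms: clean train/test plus noisy test mixtures."""

    train: list
    test: list
    noisy_test: dict  # snr_db -> list of (waveform, label)
    sample_rate: int


def mix_at_snr(sig: np.ndarray, noise: np.ndarray, snr_db: float) -> np.ndarray:
    """Add noise scaled so 10 log10(P_signal / P_noise) equals ``snr_db``."""
    p_sig = float(np.mean(sig ** 2))
    p_noise = float(np.mean(noise ** 2))
    if p_sig == 0.0:
        raise ValueError("cannot set an SNR for a zero-power signal")
    scale = math.sqrt(p_sig / (p_noise * 10.0 ** (snr_db / 10.0)))
    return sig + scale * noise


def _make_noise(rng, n, kind):
    x = rng.standard_normal(n)
    if kind == "modulated":
        t = np.arange(n)
        x = x * (1.0 + 0.8 * np.sin(2 * np.pi * 5.0 * t / 16000.0))
    return x


def synth_event_corpus(spec: CorpusSpec = CorpusSpec()) -> EventCorpus:
    """Generate a reproducible labelled corpus of synthetic sound events.

    Each event is peak-normalized; noisy test mixtures are produced for
    every SNR in ``spec.snr_list``.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.sample_rate))

    def make_set(count):
        out = []
        for label in spec.classes:
            gen = _CLASS_GENERATORS[label]
            for _ in range(count):
                x = np.asarray(gen(rng, n, spec.sample_rate), dtype=float)
                peak = np.max(np.abs(x))
                out.append((x / peak if peak > 0 else x, label))
        return out

    train = make_set(spec.n_train)
    test = make_set(spec.n_test)
    noisy = {}
    for snr in spec.snr_list:
        noisy[snr] = [
            (mix_at_snr(x, _make_noise(rng, n, spec.noise_kind), snr), label)
            for x, label in test
        ]
    return EventCorpus(train=train, test=test, noisy_test=noisy,
                       sample_rate=spec.sample_rate)


# ---------------------------------------------------------------------------
# Classification harness

def event_vector(features: FeatureMatrix) -> np.ndarray:
    """Pool a frame-wise feature matrix into one event vector (mean + std)."""
    return np.concatenate([features.values.mean(axis=0),
                           features.values.std(axis=0)])


@dataclass
class ClassifierConfig:
    """RBF-SVM settings: grids for the penalty C and kernel width gamma,
    searched by cross-validation."""

    c_grid: tuple = (0.1, 1.0, 10.0, 100.0)
    gamma_grid: tuple = ("scale", 0.01, 0.1)
    n_folds: int = 5


@dataclass
class ClassificationReport:
    accuracy: float
    confusion: pd.DataFrame
    best_params: dict

    def summary(self) -> str:
        lines = [f"accuracy: {self.accuracy:.3f}",
                 f"best params: {self.best_params}",
                 "confusion (rows true, cols predicted):",
                 self.confusion.to_string()]
        return "\n".join(lines)


def classify(train_X, train_y, test_X, test_y,
             config: ClassifierConfig = ClassifierConfig()) -> ClassificationReport:
    """One-vs-all RBF-SVM classification with winner-take-all decisions.

    Hyperparameters are grid-searched with ``n_folds``-fold
    cross-validation on the training set; features are standardized with
    training statistics.
    """
    train_X = np.asarray(train_X)
    test_X = np.asarray(test_X)
    train_y = np.asarray(train_y)
    test_y = np.asarray(test_y)
    classes = np.unique(train_y)
    if classes.size < 2:
        raise ValueError("training set must contain at least 2 classes")

    scaler = StandardScaler().fit(train_X)
    Xtr = scaler.transform(train_X)
    Xte = scaler.transform(test_X)

    n_folds = min(config.n_folds, int(np.min(np.bincount(
        np.searchsorted(classes, train_y)))))
    search = GridSearchCV(
        SVC(kernel="rbf"),
        {"C": list(config.c_grid), "gamma": list(config.gamma_grid)},
        cv=max(2, n_folds),
    )
    search.fit(Xtr, train_y)
    model = OneVsRestClassifier(SVC(kernel="rbf", **search.best_params_))
    model.fit(Xtr, train_y)
    # winner-take-all over the per-class decision values
    scores = model.decision_function(Xte)
    if scores.ndim == 1:  # two-class edge case
        pred = np.where(scores > 0, model.classes_[1], model.classes_[0])
    else:
        pred = model.classes_[np.argmax(scores, axis=1)]
    accuracy = float(np.mean(pred == test_y))
    confusion = pd.crosstab(pd.Series(test_y, name="true"),
                            pd.Series(pred, name="pred"),
                            dropna=False).reindex(index=classes, columns=classes,
                                                  fill_value=0)
    return ClassificationReport(accuracy=accuracy, confusion=confusion,
                                best_params=dict(search.best_params_))
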