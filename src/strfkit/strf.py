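"""STRF estimation by ridge-regularized reverse correlation.

The spike-triggered average (STA) of a zero-mean stimulus ensemble,

    h_STA = <s r>,

is whitened and regularized through ridge regression,

    h_ridge = <s s^T + lambda I>^{-1} <s r>,

with the regularization parameter lambda selected by 5-fold
cross-validation (highest mean held-out Pearson correlation between
predicted and observed responses).  Coefficient significance is assessed
by a bootstrap: the estimate is recomputed on 1000 random 20% subsamples
of the response bins, and coefficients whose bootstrap mean does not
differ from zero (two-sided z-test, p < 0.05) are set to 0.  Isolated
non-zero pixels (all 8 neighbours zero) are removed as insular artifacts.

The model surface follows the statsmodels convention:
``STRFModel(ensemble).fit()`` returns :class:`STRFResults` carrying the
estimate, its bootstrap uncertainty, the selected lambda and the
cross-validated prediction correlation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .periphery import BarkSpectrogram

__all__ = [
    "StimulusEnsemble",
    "RidgeConfig",
    "STRF",
    "STRFModel",
    "STRFResults",
    "sta",
    "ridge_sta",
    "select_lambda",
    "bootstrap_mask",
    "remove_insular_pixels",
    "predict_response",
]


@dataclass
class RidgeConfig:
    """Estimator settings.

    Attributes
    ----------
    lambda_grid : array_like or None
        Candidate regularization parameters; None selects a logarithmic
        grid 1e-4 ... 1e4 times the mean Gram diagonal.
    n_folds : int
        Cross-validation folds for lambda selection.
    n_boot : int
        Bootstrap replicates for coefficient significance.
    boot_fraction : float
        Fraction of response bins drawn (without replacement) per replicate.
    alpha : float
        Two-sided significance level of the coefficient z-test.
    min_correlation : float
        Inclusion threshold on the cross-validated prediction correlation.
    """

    lambda_grid: object = None
    n_folds: int = 5
    n_boot: int = 1000
    boot_fraction: float = 0.2
    alpha: float = 0.05
    min_correlation: float = 0.25

    def __post_init__(self):
        if not 0.0 < self.boot_fraction <= 1.0:
            raise ValueError("boot_fraction must be in (0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.lambda_grid is not None:
            grid = np.asarray(self.lambda_grid, dtype=float)
            if grid.size == 0 or np.any(grid < 0):
                raise ValueError("lambda_grid must be non-empty and nonnegative")


class StimulusEnsemble:
    """Paired stimulus vectors and response values for reverse correlation.

    Rows of ``vectors`` are spectro-temporal stimulus patterns (flattened
    channels x frames windows) preceding each response bin; columns are
    mean-centered on construction, matching the zero-mean stimulus
    assumption of the STA.

    Parameters
    ----------
    vectors : ndarray, shape (N, D)
    responses : ndarray, shape (N,)
    patch_shape : tuple or None
        (channels, frames) shape that a D-vector reshapes to.
    center : bool
        Remove column means (default True; the means are retained in
        ``column_means``).
    """

    def __init__(self, vectors, responses, patch_shape=None, center=True):
        vectors = np.asarray(vectors, dtype=float)
        responses = np.asarray(responses, dtype=float)
        if vectors.ndim != 2:
            raise ValueError("vectors must be a 2D (N x D) array")
        if responses.shape != (vectors.shape[0],):
            raise ValueError("responses must be a length-N vector")
        if vectors.shape[0] == 0 or vectors.shape[1] == 0:
            raise ValueError("ensemble must be non-empty")
        if patch_shape is not None and int(np.prod(patch_shape)) != vectors.shape[1]:
            raise ValueError("patch_shape does not match D")
        self.column_means = vectors.mean(axis=0)
        self.vectors = vectors - self.column_means if center else vectors
        self.responses = responses
        self.patch_shape = tuple(patch_shape) if patch_shape is not None else None

    @property
    def n_samples(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_dim(self) -> int:
        return self.vectors.shape[1]

    @classmethod
    def from_spectrogram(cls, spec: BarkSpectrogram, responses, n_frames: int = 50,
                         center: bool = True) -> "StimulusEnsemble":
        """Build lagged stimulus windows from a spectrogram.

        Row t holds the ``n_frames``-frame window ending at frame
        ``t + n_frames - 1`` (the stimulus *preceding* that response bin);
        ``responses`` must be per-frame values aligned to the spectrogram
        (only bins with a complete preceding window are used).
        """
        values = np.asarray(spec.values, dtype=float)
        responses = np.asarray(responses, dtype=float)
        n_ch, n_fr = values.shape
        if responses.shape != (n_fr,):
            raise ValueError("responses must have one value per spectrogram frame")
        if n_fr < n_frames:
            raise ValueError("spectrogram shorter than one stimulus window")
        n = n_fr - n_frames + 1
        windows = np.lib.stride_tricks.sliding_window_view(values, n_frames, axis=1)
        # (n_ch, n, n_frames) -> (n, n_ch * n_frames)
        vectors = np.ascontiguousarray(windows.transpose(1, 0, 2)).reshape(n, -1)
        return cls(vectors, responses[n_frames - 1:], patch_shape=(n_ch, n_frames),
                   center=center)


@dataclass
class STRF:
    """An estimated spectro-temporal receptive field.

    ``patch`` is zero wherever ``mask`` is False; ``cv_correlation`` is the
    mean held-out prediction correlation at the selected ``lambda_star``.
    """

    patch: np.ndarray = field(repr=False)
    mask: np.ndarray = field(repr=False)
    lambda_star: float
    cv_correlation: float

    @property
    def included(self) -> bool:
        """Inclusion rule: mean held-out correlation of at least 0.25."""
        return self.cv_correlation >= 0.25

    def save(self, path_prefix: str):
        np.savez(f"{path_prefix}.npz", patch=self.patch, mask=self.mask)
        with open(f"{path_prefix}.json", "w") as fh:
            json.dump(
                {
                    "lambda_star": self.lambda_star,
                    "cv_correlation": self.cv_correlation,
                    "mask_density": float(self.mask.mean()),
                },
                fh,
                indent=1,
            )

    @classmethod
    def load(cls, path_prefix: str) -> "STRF":
        with np.load(f"{path_prefix}.npz") as data:
            patch, mask = data["patch"], data["mask"]
        with open(f"{path_prefix}.json") as fh:
            meta = json.load(fh)
        return cls(patch=patch, mask=mask, lambda_star=meta["lambda_star"],
                   cv_correlation=meta["cv_correlation"])


def sta(ensemble: StimulusEnsemble) -> np.ndarray:
    """Spike-triggered average ``(1/N) sum_n s_n r_n`` (D-vector)."""
    return ensemble.vectors.T @ ensemble.responses / ensemble.n_samples


def _solve_ridge(gram: np.ndarray, cross: np.ndarray, lam: float) -> np.ndarray:
    d = gram.shape[0]
    if lam == 0.0:
        try:
            return linalg.solve(gram, cross, assume_a="pos")
        except linalg.LinAlgError:
            warnings.warn("singular Gram matrix at lambda=0; using pseudo-inverse",
                          stacklevel=3)
            return linalg.lstsq(gram, cross)[0]
    return linalg.solve(gram + lam * np.eye(d), cross, assume_a="pos")


def ridge_sta(ensemble: StimulusEnsemble, lam: float) -> np.ndarray:
    """Ridge-regularized whitened STA: solves ``(S^T S/N + lambda I) h = S^T r/N``."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    X, r = ensemble.vectors, ensemble.responses
    n = ensemble.n_samples
    gram = X.T @ X / n
    cross = X.T @ r / n
    return _solve_ridge(gram, cross, lam)


def predict_response(strf, ensemble: StimulusEnsemble) -> np.ndarray:
    """Linear response prediction ``r_hat_n = s_n . h``."""
    h = strf.patch.ravel() if isinstance(strf, STRF) else np.asarray(strf).ravel()
    if h.size != ensemble.n_dim:
        raise ValueError(f"filter size {h.size} does not match ensemble D={ensemble.n_dim}")
    return ensemble.vectors @ h


def default_lambda_grid(ensemble: StimulusEnsemble, n_points: int = 9) -> np.ndarray:
    """Logarithmic grid 1e-4 ... 1e4 times the mean Gram diagonal."""
    scale = float(np.mean(ensemble.vectors ** 2))
    if scale == 0.0:
        scale = 1.0
    return scale * np.logspace(-4, 4, n_points)


def _fold_slices(n: int, n_folds: int):
    """Contiguous folds (lagged windows overlap, so blocks leak less than
    interleaved splits)."""
    edges = np.linspace(0, n, n_folds + 1).astype(int)
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


class RidgeCV:
    """Precomputed cross-validation machinery for one design matrix.

    Eigendecomposes each fold's training Gram once so that the ridge
    solution for any (lambda, response) pair is a cheap rotation; lets
    lambda selection and repeated estimation (e.g. over many simulated
    neurons sharing one stimulus) reuse the expensive factorizations.
    """

    def __init__(self, X: np.ndarray, n_folds: int = 5):
        self.X = X
        n = X.shape[0]
        self.folds = []
        full_gram = X.T @ X
        for sl in _fold_slices(n, n_folds):
            X_te = X[sl]
            gram_tr = (full_gram - X_te.T @ X_te) / (n - X_te.shape[0])
            evals, evecs = linalg.eigh(gram_tr)
            self.folds.append((sl, np.maximum(evals, 0.0), evecs))
        self._full = None
        self._full_gram = full_gram / n
        self._proj_te: dict = {}  # fold index -> X_test @ evecs (cached)

    def _fold_solution(self, fold, r, lam):
        sl, evals, evecs = fold
        n = self.X.shape[0]
        mask = np.ones(n, dtype=bool)
        mask[sl] = False
        X_tr, r_tr = self.X[mask], r[mask]
        cross = evecs.T @ (X_tr.T @ r_tr / X_tr.shape[0])
        return evecs @ (cross / (evals + lam)), sl

    def cv_correlations(self, r: np.ndarray, grid) -> np.ndarray:
        """Mean held-out Pearson correlation for every lambda in the grid."""
        grid = np.asarray(grid, dtype=float)
        corrs = np.full((len(self.folds), grid.size), np.nan)
        for i, fold in enumerate(self.folds):
            sl, evals, evecs = fold
            n = self.X.shape[0]
            mask = np.ones(n, dtype=bool)
            mask[sl] = False
            X_tr, r_tr = self.X[mask], r[mask]
            X_te, r_te = self.X[sl], r[sl]
            if np.std(r_te) == 0.0:
                warnings.warn("constant responses in a CV fold; fold skipped",
                              stacklevel=3)
                continue
            cross = evecs.T @ (X_tr.T @ r_tr / X_tr.shape[0])
            if i not in self._proj_te:
                self._proj_te[i] = X_te @ evecs
            proj_te = self._proj_te[i]
            for k, lam in enumerate(grid):
                pred = proj_te @ (cross / (evals + lam))
                if np.std(pred) == 0.0:
                    continue
                corrs[i, k] = np.corrcoef(pred, r_te)[0, 1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(corrs, axis=0)

    def select(self, r: np.ndarray, grid) -> tuple:
        """(lambda_star, cv_correlation); ties broken toward larger lambda."""
        grid = np.asarray(grid, dtype=float)
        mean_corr = self.cv_correlations(r, grid)
        if np.all(np.isnan(mean_corr)):
            raise ValueError("cross-validation failed in every fold")
        order = np.argsort(grid)  # ascending; later (larger lambda) wins ties
        best = max(order, key=lambda k: (np.nan_to_num(mean_corr[k], nan=-np.inf), grid[k]))
        return float(grid[best]), float(mean_corr[best])

    def solve_full(self, r: np.ndarray, lam: float) -> np.ndarray:
        """Ridge solution on the full ensemble, reusing one eigendecomposition."""
        if self._full is None:
            evals, evecs = linalg.eigh(self._full_gram)
            self._full = (np.maximum(evals, 0.0), evecs)
        evals, evecs = self._full
        cross = evecs.T @ (self.X.T @ r / self.X.shape[0])
        return evecs @ (cross / (evals + lam))


def select_lambda(ensemble: StimulusEnsemble, config: RidgeConfig = RidgeConfig()):
    """Cross-validated regularization choice.

    Returns
    -------
    (lambda_star, cv_correlation)
        The grid value maximizing the mean held-out Pearson correlation
        between predicted and observed responses, and that correlation.
    """
    grid = (np.asarray(config.lambda_grid, dtype=float)
            if config.lambda_grid is not None else default_lambda_grid(ensemble))
    cv = RidgeCV(ensemble.vectors, config.n_folds)
    return cv.select(ensemble.responses, grid)


def bootstrap_mask(ensemble: StimulusEnsemble, lambda_star: float,
                   config: RidgeConfig = RidgeConfig(), seed=None) -> STRF:
    """Bootstrap significance mask at a fixed regularization parameter.

    Recomputes the ridge estimate on ``n_boot`` random subsamples (without
    replacement, ``boot_fraction`` of the response bins each), then keeps a
    coefficient iff its bootstrap mean differs from zero in a two-sided
    z-test at level alpha.  The spread of m-out-of-N subsample estimates
    overstates the full-sample standard error by sqrt(N/m - 1), so the
    bootstrap standard deviation is rescaled by sqrt((m/N) / (1 - m/N))
    before the test; this calibrates the keep rate to ~alpha under the
    null (responses independent of the stimulus).  Masked coefficients of
    the full-data estimate are set to exactly 0.
    """
    X, r = ensemble.vectors, ensemble.responses
    n, d = X.shape
    m = max(1, int(round(config.boot_fraction * n)))
    streams = np.random.SeedSequence(seed).spawn(config.n_boot)
    s1 = np.zeros(d)
    s2 = np.zeros(d)
    for ss in streams:
        rng = np.random.default_rng(ss)
        idx = rng.choice(n, size=m, replace=False)
        Xb, rb = X[idx], r[idx]
        gram = Xb.T @ Xb / m
        cross = Xb.T @ rb / m
        h = _solve_ridge(gram, cross, lambda_star)
        s1 += h
        s2 += h * h
    mu = s1 / config.n_boot
    var = np.maximum(s2 / config.n_boot - mu ** 2, 0.0)
    # m-out-of-N subsampling variance correction (exact for mean-like
    # statistics under simple random sampling without replacement)
    if m < n:
        var *= (m / n) / (1.0 - m / n)
    se = np.sqrt(var)
    z_crit = stats.norm.ppf(1.0 - config.alpha / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(mu) / se
    keep = np.where(se > 0, z > z_crit, mu != 0)

    h_full = ridge_sta(ensemble, lambda_star)
    patch_shape = ensemble.patch_shape or (1, d)
    patch = np.where(keep, h_full, 0.0).reshape(patch_shape)
    mask = keep.reshape(patch_shape)
    return STRF(patch=patch, mask=mask, lambda_star=lambda_star, cv_correlation=np.nan)


def remove_insular_pixels(strf):
    """Zero out non-zero pixels whose existing 8-neighbourhood is all zero.

    Accepts an :class:`STRF` (returns a new STRF with patch and mask
    cleaned) or a bare 2D array.  Single simultaneous pass; idempotent,
    since a removed pixel by definition contributed to no other pixel's
    neighbourhood.
    """
    if isinstance(strf, STRF):
        cleaned = remove_insular_pixels(strf.patch)
        return STRF(patch=cleaned, mask=cleaned != 0, lambda_star=strf.lambda_star,
                    cv_correlation=strf.cv_correlation)
    patch = np.asarray(strf, dtype=float)
    if patch.ndim != 2:
        raise ValueError("expected a 2D patch")
    nz = patch != 0
    padded = np.pad(nz, 1)
    neighbours = np.zeros(patch.shape, dtype=int)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            neighbours += padded[1 + di : 1 + di + patch.shape[0],
                                 1 + dj : 1 + dj + patch.shape[1]]
    insular = nz & (neighbours == 0)
    out = patch.copy()
    out[insular] = 0.0
    return out


class STRFModel:
    """Ridge reverse-correlation model of one neuron's STRF.

    Parameters
    ----------
    ensemble : StimulusEnsemble
        Paired stimulus windows and response values.
    config : RidgeConfig
        Estimator settings.

    Examples
    --------
    >>> model = STRFModel.from_spectrogram(spec, mean_counts)  # doctest: +SKIP
    >>> res = model.fit(seed=0)                                # doctest: +SKIP
    >>> res.strf.patch.shape                                   # doctest: +SKIP
    (21, 50)
    """

    def __init__(self, ensemble: StimulusEnsemble, config: RidgeConfig = RidgeConfig()):
        self.ensemble = ensemble
        self.config = config

    @classmethod
    def from_spectrogram(cls, spec: BarkSpectrogram, responses, n_frames: int = 50,
                         config: RidgeConfig = RidgeConfig()) -> "STRFModel":
        return cls(StimulusEnsemble.from_spectrogram(spec, responses, n_frames), config)

    def fit(self, seed=None, mask: bool = True, clean: bool = True) -> "STRFResults":
        """Select lambda, estimate, and (optionally) bootstrap-mask the STRF."""
        cfg = self.config
        grid = (np.asarray(cfg.lambda_grid, dtype=float)
                if cfg.lambda_grid is not None else default_lambda_grid(self.ensemble))
        cv = RidgeCV(self.ensemble.vectors, cfg.n_folds)
        lam, cv_corr = cv.select(self.ensemble.responses, grid)
        h_full = cv.solve_full(self.ensemble.responses, lam)
        shape = self.ensemble.patch_shape or (1, self.ensemble.n_dim)

        boot_mean = boot_sd = None
        if mask:
            masked = bootstrap_mask(self.ensemble, lam, cfg, seed=seed)
            patch, keep = masked.patch, masked.mask
        else:
            patch = h_full.reshape(shape)
            keep = np.ones(shape, dtype=bool)
        if clean:
            patch = remove_insular_pixels(patch)
            keep = patch != 0 if mask else keep
        strf = STRF(patch=patch, mask=keep, lambda_star=lam, cv_correlation=cv_corr)
        return STRFResults(self, strf, raw_estimate=h_full.reshape(shape),
                           lambda_grid=grid)


@dataclass
class STRFResults:
    """Fitted STRF with its selection diagnostics."""

    model: STRFModel
    strf: STRF
    raw_estimate: np.ndarray = field(repr=False)
    lambda_grid: np.ndarray = field(repr=False)

    @property
    def lambda_star(self) -> float:
        return self.strf.lambda_star

    @property
    def cv_correlation(self) -> float:
        return self.strf.cv_correlation

    @property
    def included(self) -> bool:
        return self.strf.cv_correlation >= self.model.config.min_correlation

    def predict(self, ensemble: StimulusEnsemble | None = None) -> np.ndarray:
        return predict_response(self.strf, ensemble or self.model.ensemble)

    def summary(self) -> str:
        s = self.strf
        lines = [
            "STRF ridge reverse-correlation results",
            "=" * 42,
            f"{'samples':<28}{self.model.ensemble.n_samples:>14}",
            f"{'dimensions':<28}{self.model.ensemble.n_dim:>14}",
            f"{'lambda*':<28}{s.lambda_star:>14.4g}",
            f"{'cv prediction correlation':<28}{s.cv_correlation:>14.3f}",
            f"{'mask density':<28}{float(s.mask.mean()):>14.3f}",
            f"{'included (cv corr >= 0.25)':<28}{str(self.included):>14}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Render the masked STRF patch (time on x, Bark channel on y)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        v = np.max(np.abs(self.strf.patch)) or 1.0
        ax.imshow(self.strf.patch, aspect="auto", origin="lower", cmap="RdBu_r",
                  vmin=-v, vmax=v)
        ax.set_xlabel("time (frames)")
        ax.set_ylabel("Bark channel")
        return ax
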