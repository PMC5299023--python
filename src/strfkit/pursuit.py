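"""Two-dimensional matching pursuit over a Gabor dictionary.

Greedy sparse decomposition of STRF patches: at each iteration the
(atom, part, shift) whose unit-norm shifted patch has the largest absolute
inner product with the residual is selected, its projection is subtracted,
and the process repeats until the Pearson correlation between the target
and the cumulative reconstruction reaches a threshold theta.

Two summary statistics characterize a decomposition:

* kappa ("diagonality" / spectro-temporality): per selected atom, the L1
  norm of the L2-normalized modulation vector (1 for purely temporal or
  purely spectral atoms, sqrt(2) for |w_t| = |w_s| in normalized units);
  the decomposition's kappa is the mean over its entries.
* eta (atom importance): per dictionary atom, the sum of absolute MP
  weights it accrues over all iterations of all decompositions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gabor import GaborBank

__all__ = [
    "MPEntry",
    "MPResults",
    "MatchingPursuit",
    "ImportanceTable",
    "mp_decompose",
    "reconstruct",
    "kappa_modulation",
    "kappa_decomposition",
    "atom_importance",
    "atom_count_histogram",
    "kappa_vs_theta",
]


def kappa_modulation(omega_t: float, omega_s: float) -> float:
    """Diagonality of a single modulation vector (L1 of its L2 unit vector).

    ``(|w_t| + |w_s|) / sqrt(w_t^2 + w_s^2)``; ranges from 1 (axis-aligned)
    to sqrt(2) (|w_t| = |w_s|).  The components must share a common unit
    (dictionary layers pass cycles-per-sample values).  The zero vector is
    an envelope-only (DC) atom, trivially separable: returns 1.0.
    """
    norm = math.hypot(omega_t, omega_s)
    if norm == 0.0:
        return 1.0
    return (abs(omega_t) + abs(omega_s)) / norm


@dataclass
class MPEntry:
    """One matching-pursuit selection."""

    atom_id: int
    part: str
    time_shift: int
    freq_shift: int
    weight: float


@dataclass
class MPResults:
    """Result of a matching-pursuit decomposition.

    Attributes
    ----------
    entries : list of MPEntry
        Ordered selections (first = largest projection).
    residual : ndarray
        Target minus reconstruction.
    recon_correlation : ndarray
        Pearson correlation between target and cumulative reconstruction
        after each iteration (non-decreasing).
    converged : bool
        Whether the threshold theta was reached before max_iter.
    """

    entries: list
    residual: np.ndarray = field(repr=False)
    recon_correlation: np.ndarray = field(repr=False)
    theta: float
    converged: bool
    bank: GaborBank = field(repr=False)
    target: np.ndarray = field(repr=False)

    @property
    def n_iter(self) -> int:
        return len(self.entries)

    @property
    def kappa(self) -> float:
        return kappa_decomposition(self)

    def reconstruct(self) -> np.ndarray:
        return reconstruct(self, self.target.shape)

    def to_dict(self) -> dict:
        return {
            "theta": self.theta,
            "converged": self.converged,
            "kappa": self.kappa,
            "recon_correlation": list(map(float, self.recon_correlation)),
            "entries": [
                {
                    "atom_id": e.atom_id,
                    "part": e.part,
                    "time_shift": e.time_shift,
                    "freq_shift": e.freq_shift,
                    "weight": e.weight,
                }
                for e in self.entries
            ],
        }


def _shifted_patch(patch: np.ndarray, t_shift: int, f_shift: int) -> np.ndarray:
    """Shift a patch within its own frame, zero-filling; no wrap-around."""
    out = np.zeros_like(patch)
    n_f, n_t = patch.shape
    f0, f1 = max(0, f_shift), min(n_f, n_f + f_shift)
    t0, t1 = max(0, t_shift), min(n_t, n_t + t_shift)
    out[f0:f1, t0:t1] = patch[f0 - f_shift : f1 - f_shift, t0 - t_shift : t1 - t_shift]
    return out


class _Dictionary:
    """Flattened, unit-norm, shifted-atom dictionary for one bank."""

    def __init__(self, bank: GaborBank, t_shifts, f_shifts):
        n_f, n_t = bank.shape
        rows, meta = [], []
        for aid, atom in enumerate(bank.atoms):
            for fs in f_shifts:
                for ts in t_shifts:
                    p = _shifted_patch(atom.patch, ts, fs) if (ts or fs) else atom.patch
                    nrm = np.linalg.norm(p)
                    if nrm < 1e-12:
                        continue
                    rows.append((p / nrm).ravel())
                    meta.append((aid, atom.part, ts, fs))
        self.matrix = np.asarray(rows)
        self.meta = meta
        self.shape = (n_f, n_t)


_DICT_CACHE: dict = {}


def _get_dictionary(bank: GaborBank, t_shifts, f_shifts) -> _Dictionary:
    key = (id(bank), tuple(t_shifts), tuple(f_shifts))
    if key not in _DICT_CACHE:
        _DICT_CACHE.clear()  # keep at most one bank's dictionary around
        _DICT_CACHE[key] = _Dictionary(bank, t_shifts, f_shifts)
    return _DICT_CACHE[key]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


class MatchingPursuit:
    """Greedy 2D matching pursuit of one target patch over a Gabor bank.

    Parameters
    ----------
    target : ndarray
        Real (channels x frames) patch, must be non-zero and match the
        bank's patch shape.
    bank : GaborBank
        Dictionary of unit-norm real atoms.
    theta : float
        Termination threshold on the Pearson correlation between target
        and reconstruction, in (0, 1].
    max_iter : int
        Iteration cap; failure to reach theta is flagged, not silent.
    t_shifts, f_shifts : sequence of int or None
        Allowed temporal / spectral shifts of atoms (atom center offset in
        frames / channels).  Temporal shifts default to every placement
        within the patch; spectral shifts default to none (full-height
        atoms).  Clipped shifted atoms are renormalized to unit norm.
    """

    def __init__(self, target, bank: GaborBank, theta: float = 0.8, max_iter: int = 50,
                 t_shifts=None, f_shifts=(0,)):
        target = np.asarray(target, dtype=float)
        if not np.any(target):
            raise ValueError("target patch is identically zero")
        if not 0.0 < theta <= 1.0:
            raise ValueError("theta must be in (0, 1]")
        if target.shape != bank.shape:
            raise ValueError(
                f"target shape {target.shape} does not match bank patch shape {bank.shape}"
            )
        n_t = bank.shape[1]
        if t_shifts is None:
            t_shifts = range(-(n_t // 2), n_t - n_t // 2)
        self.target = target
        self.bank = bank
        self.theta = theta
        self.max_iter = max_iter
        self._dict = _get_dictionary(bank, t_shifts, f_shifts)

    def fit(self) -> MPResults:
        D = self._dict.matrix
        meta = self._dict.meta
        target = self.target.ravel()
        residual = target.copy()
        recon = np.zeros_like(target)
        entries, corrs = [], []
        converged = False
        for _ in range(self.max_iter):
            proj = D @ residual
            j = int(np.argmax(np.abs(proj)))
            w = float(proj[j])
            if w == 0.0:  # residual orthogonal to the whole dictionary
                break
            aid, part, ts, fs = meta[j]
            entries.append(MPEntry(aid, part, ts, fs, w))
            residual -= w * D[j]
            recon += w * D[j]
            corrs.append(_pearson(target, recon))
            if corrs[-1] >= self.theta:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"matching pursuit stopped at {len(entries)} iterations with "
                f"correlation {corrs[-1] if corrs else 0.0:.3f} < theta={self.theta}",
                stacklevel=2,
            )
        return MPResults(
            entries=entries,
            residual=residual.reshape(self.target.shape),
            recon_correlation=np.asarray(corrs),
            theta=self.theta,
            converged=converged,
            bank=self.bank,
            target=self.target,
        )


def mp_decompose(target, bank: GaborBank, theta: float = 0.8, max_iter: int = 50,
                 t_shifts=None, f_shifts=(0,)) -> MPResults:
    """Decompose ``target`` over ``bank``; see :class:`MatchingPursuit`."""
    return MatchingPursuit(target, bank, theta, max_iter, t_shifts, f_shifts).fit()


def reconstruct(dec: MPResults, shape=None) -> np.ndarray:
    """Sum of weight x shifted unit-norm atom over the decomposition's entries."""
    if shape is None:
        shape = dec.bank.shape
    out = np.zeros(shape)
    for e in dec.entries:
        if not 0 <= e.atom_id < len(dec.bank.atoms):
            raise KeyError(f"unknown atom_id {e.atom_id}")
        atom = dec.bank.atoms[e.atom_id]
        if atom.part != e.part:
            # atom ids address the real-atom list directly; part is metadata
            raise KeyError(f"atom {e.atom_id} is part={atom.part!r}, entry says {e.part!r}")
        p = _shifted_patch(atom.patch, e.time_shift, e.freq_shift)
        nrm = np.linalg.norm(p)
        out += e.weight * p / nrm
    return out


def _entry_kappas(dec: MPResults) -> np.ndarray:
    ks = []
    for e in dec.entries:
        atom = dec.bank.atoms[e.atom_id]
        wt, ws = dec.bank.normalized_modulation(atom)
        ks.append(kappa_modulation(wt, ws))
    return np.asarray(ks)


def kappa_decomposition(dec: MPResults) -> float:
    """Mean diagonality over the decomposition's entries (in [1, sqrt(2)])."""
    if dec.n_iter == 0:
        raise ValueError("kappa is undefined for an empty decomposition")
    return float(_entry_kappas(dec).mean())


@dataclass
class ImportanceTable:
    """Per-atom importance eta: sum of |weight| over all decompositions."""

    eta: np.ndarray
    n_strfs: int
    bank: GaborBank = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "atom_id": i,
                "omega_t": a.omega_t,
                "omega_s": a.omega_s,
                "part": a.part,
                "eta": self.eta[i],
            }
            for i, a in enumerate(self.bank.atoms)
        ]
        return pd.DataFrame(rows)


def atom_importance(decs, bank: GaborBank) -> ImportanceTable:
    """Accumulate eta_j = sum over iterations and targets of |gamma_ijk|."""
    eta = np.zeros(len(bank.atoms))
    for dec in decs:
        for e in dec.entries:
            eta[e.atom_id] += abs(e.weight)
    return ImportanceTable(eta=eta, n_strfs=len(list(decs)), bank=bank)


def atom_count_histogram(decs) -> dict:
    """Histogram of atoms-per-decomposition: {n_iter: count}."""
    counts: dict = {}
    for dec in decs:
        counts[dec.n_iter] = counts.get(dec.n_iter, 0) + 1
    return dict(sorted(counts.items()))


def kappa_vs_theta(targets, bank: GaborBank, theta_grid, max_iter: int = 50,
                   t_shifts=None, f_shifts=(0,)) -> pd.DataFrame:
    """Mean kappa over targets at each reconstruction threshold theta."""
    theta_grid = list(theta_grid)
    if any(t2 <= t1 for t1, t2 in zip(theta_grid, theta_grid[1:])):
        raise ValueError("theta_grid must be strictly increasing")
    rows = []
    for theta in theta_grid:
        kappas = [
            kappa_decomposition(
                mp_decompose(t, bank, theta, max_iter, t_shifts, f_shifts)
            )
            for t in targets
        ]
        rows.append({"theta": theta, "kappa": float(np.mean(kappas))})
    return pd.DataFrame(rows)
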