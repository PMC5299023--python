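"""Complex spectro-temporal Gabor atoms and the modulation filter bank.

A Gabor atom is a separable product of complex sinusoidal carriers and Hann
envelopes along the time and frequency axes of a Bark spectrogram patch:

    g(t, f) = exp(i 2 pi w_t t) exp(i 2 pi w_s f) h_{b_t}(t) h_{b_s}(f)

with temporal modulation w_t in Hz, spectral modulation w_s in cyc/Bark,
and center-peaked Hann envelopes of widths b_t (ms) and b_s (Bark).  The
bank covers the modulation plane up to half the frame-rate Nyquist
(125 Hz at a 2 ms frame period) and half the channel Nyquist
(0.25 cyc/Bark at 1-Bark spacing), with constant-Q envelope widths capped
at the 21-band x 100 ms patch.  For dictionary use the real and imaginary
parts are emitted as separate real-valued atoms, mean-subtracted and
normalized to unit Euclidean norm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .periphery import PeripheryConfig

__all__ = [
    "GaborAtom",
    "GaborBank",
    "hann_envelope",
    "gabor_atom",
    "build_bank",
]

# Half-height full width of the modulation transfer function of a Hann
# envelope with support b, expressed in units of 1/b.
_HANN_MTF_HALFWIDTH = 1.44


def hann_envelope(x, b):
    """Center-peaked Hann envelope of support width ``b``.

    ``0.5 + 0.5 cos(2 pi x / b)`` for ``|x| < b/2`` and 0 elsewhere;
    peaks at 1 for x = 0.

    Parameters
    ----------
    x : float or array_like
        Axis coordinate relative to the envelope center.
    b : float
        Full support width, must be positive.
    """
    if b <= 0:
        raise ValueError("envelope width b must be positive")
    x = np.asarray(x, dtype=float)
    inside = np.abs(x) < b / 2.0
    out = np.where(inside, 0.5 + 0.5 * np.cos(2.0 * np.pi * x / b), 0.0)
    return out if out.ndim else float(out)


@dataclass
class GaborAtom:
    """One spectro-temporal Gabor atom.

    Attributes
    ----------
    omega_t : float
        Temporal modulation frequency in Hz (signed).
    omega_s : float
        Spectral modulation frequency in cyc/Bark (signed).
    b_t : float
        Temporal envelope support width in ms.
    b_s : float
        Spectral envelope support width in Bark.
    patch : ndarray
        (channels x frames) patch; complex for the full atom, real for a
        realized dictionary atom.
    part : str or None
        None for the complex atom; "real" or "imag" for a real-valued
        dictionary realization.
    """

    omega_t: float
    omega_s: float
    b_t: float
    b_s: float
    patch: np.ndarray = field(repr=False)
    part: str | None = None

    @property
    def shape(self):
        return self.patch.shape

    @property
    def is_dc(self) -> bool:
        return self.omega_t == 0.0 and self.omega_s == 0.0


def gabor_atom(
    omega_t: float,
    omega_s: float,
    b_t: float,
    b_s: float,
    shape=(21, 50),
    frame_period_ms: float = 2.0,
    channel_spacing_bark: float = 1.0,
    allow_truncation: bool = False,
) -> GaborAtom:
    """Construct a complex Gabor atom sampled on a spectrogram patch grid.

    The patch axes are centered: time samples at
    ``(k - (n_frames - 1)/2) * frame_period_ms`` and channels at
    ``(j - (n_channels - 1)/2) * channel_spacing_bark``.

    Raises
    ------
    ValueError
        If an envelope extends beyond the patch and ``allow_truncation``
        is False, or if a width is not positive.
    """
    n_f, n_t = shape
    if b_t <= 0 or b_s <= 0:
        raise ValueError("envelope widths must be positive")
    t_extent = n_t * frame_period_ms
    f_extent = n_f * channel_spacing_bark
    if (b_t > t_extent or b_s > f_extent) and not allow_truncation:
        raise ValueError(
            "envelope exceeds the patch extent "
            f"(b_t={b_t} ms vs {t_extent} ms, b_s={b_s} Bark vs {f_extent} Bark); "
            "pass allow_truncation=True to clip"
        )
    t = (np.arange(n_t) - (n_t - 1) / 2.0) * frame_period_ms
    f = (np.arange(n_f) - (n_f - 1) / 2.0) * channel_spacing_bark
    # omega_t is in Hz, t in ms
    carrier_t = np.exp(2j * np.pi * omega_t * t * 1e-3) * hann_envelope(t, b_t)
    carrier_f = np.exp(2j * np.pi * omega_s * f) * hann_envelope(f, b_s)
    patch = np.outer(carrier_f, carrier_t)
    return GaborAtom(omega_t, omega_s, b_t, b_s, patch)


def realize(atom: GaborAtom, part: str, zero_mean: bool = True) -> GaborAtom:
    """Extract the real or imaginary part of a complex atom as a real,
    optionally mean-subtracted, unit-norm dictionary atom."""
    if part not in ("real", "imag"):
        raise ValueError("part must be 'real' or 'imag'")
    p = atom.patch.real if part == "real" else atom.patch.imag
    p = p.astype(float).copy()
    if zero_mean:
        p -= p.mean()
    nrm = np.linalg.norm(p)
    if nrm == 0:
        raise ValueError(f"{part} part of atom is identically zero")
    return replace(atom, patch=p / nrm, part=part)


def _modulation_lattice(omega_max: float, cap_width: float, n_cycles: float):
    """Modulation-frequency grid for one axis.

    Envelope widths follow the constant-Q rule b = 2 * n_cycles / omega
    (one carrier period per half-height width at n_cycles = 1), capped at
    ``cap_width``.  Centers descend geometrically while uncapped so that
    adjacent modulation transfer functions cross near half height, then
    linearly (constant bandwidth) in the capped regime, and 0 (DC) is
    always included.  Units: omega in cycles per axis-unit, widths in the
    same axis unit.
    """
    rel = _HANN_MTF_HALFWIDTH / 4.0 / n_cycles  # half of the relative MTF halfwidth
    ratio = (1.0 - rel) / (1.0 + rel)
    cap_bw = _HANN_MTF_HALFWIDTH / cap_width
    omegas = []
    om = omega_max
    while om > 0 and 2.0 * n_cycles / om <= cap_width:
        omegas.append(om)
        om *= ratio
    # capped regime: linear descent by the (now constant) MTF halfwidth
    while om > cap_bw / 2.0:
        omegas.append(om)
        om -= cap_bw
    omegas.append(0.0)
    return sorted(set(omegas))


@dataclass
class GaborBank:
    """A dictionary of real-valued Gabor atoms covering the modulation plane.

    Attributes
    ----------
    atoms : list of GaborAtom
        Real-valued, zero-mean, unit-norm atoms (real/imag parts emitted
        separately).
    complex_atoms : list of GaborAtom
        The underlying complex atoms, one per modulation-lattice point.
    frame_period_ms, channel_spacing_bark : float
        Sampling of the patch grid (used to express modulations in
        normalized units, e.g. for the diagonality statistic).
    max_temporal_mod, max_spectral_mod : float
        Design maxima of the lattice (Hz, cyc/Bark).
    grid : dict
        Design metadata (per-axis lattices, constant-Q parameter).
    """

    atoms: list
    complex_atoms: list = field(repr=False)
    frame_period_ms: float = 2.0
    channel_spacing_bark: float = 1.0
    max_temporal_mod: float = 125.0
    max_spectral_mod: float = 0.25
    grid: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.atoms)

    @property
    def shape(self):
        return self.atoms[0].patch.shape

    def normalized_modulation(self, atom: GaborAtom):
        """Modulation pair in cycles per sample (frame, channel)."""
        return (
            atom.omega_t * self.frame_period_ms * 1e-3,
            atom.omega_s * self.channel_spacing_bark,
        )

    def save(self, path_prefix: str):
        """Serialize to ``<prefix>.json`` (parameters) + ``<prefix>.npz``."""
        meta = {
            "frame_period_ms": self.frame_period_ms,
            "channel_spacing_bark": self.channel_spacing_bark,
            "max_temporal_mod": self.max_temporal_mod,
            "max_spectral_mod": self.max_spectral_mod,
            "grid": self.grid,
            "atoms": [
                {
                    "omega_t": a.omega_t,
                    "omega_s": a.omega_s,
                    "b_t": a.b_t,
                    "b_s": a.b_s,
                    "part": a.part,
                }
                for a in self.atoms
            ],
        }
        with open(f"{path_prefix}.json", "w") as fh:
            json.dump(meta, fh, indent=1)
        np.savez(
            f"{path_prefix}.npz",
            patches=np.stack([a.patch for a in self.atoms]),
        )


def build_bank(
    config: PeripheryConfig = PeripheryConfig(),
    *,
    max_temporal_mod: float | None = None,
    max_spectral_mod: float | None = None,
    n_cycles: float = 1.0,
    n_frames: int = 50,
    n_channels: int = 21,
    include_negative_spectral: bool = True,
    zero_mean: bool = True,
    omega_t_grid=None,
    omega_s_grid=None,
) -> GaborBank:
    """Build the Gabor filter bank for a given periphery configuration.

    The modulation lattice spans [0, max_temporal_mod] Hz x
    [0, max_spectral_mod] cyc/Bark inclusive; the maxima default to half
    the respective Nyquist frequencies of the spectrogram grid (125 Hz and
    0.25 cyc/Bark at the default 2 ms / 1 Bark sampling).  Mixed atoms are
    emitted in both diagonal orientations (negative spectral modulation)
    when ``include_negative_spectral`` is set.  ``omega_t_grid`` /
    ``omega_s_grid`` (Hz, cyc/Bark; nonnegative, 0 = DC) override the
    constant-Q lattice on either axis, e.g. for ground-truth filter sets
    in simulation studies.
    """
    dt_ms = config.frame_period_ms
    df_bark = config.bark_bandwidth
    frame_rate = 1000.0 / dt_ms
    if max_temporal_mod is None:
        max_temporal_mod = frame_rate / 4.0
    if max_spectral_mod is None:
        max_spectral_mod = 1.0 / (4.0 * df_bark)
    if max_temporal_mod > frame_rate / 4.0 or max_spectral_mod > 1.0 / (4.0 * df_bark):
        raise ValueError("bank maxima must not exceed half-Nyquist of the grid")

    t_extent = n_frames * dt_ms  # ms
    f_extent = n_channels * df_bark  # Bark
    # lattice in cycles/ms and cycles/Bark, converted back afterwards
    if omega_t_grid is None:
        omega_t_grid = [
            1000.0 * w
            for w in _modulation_lattice(max_temporal_mod / 1000.0, t_extent, n_cycles)
        ]
    else:
        omega_t_grid = sorted(set(float(w) for w in omega_t_grid))
    if omega_s_grid is None:
        omega_s_grid = _modulation_lattice(max_spectral_mod, f_extent, n_cycles)
    else:
        omega_s_grid = sorted(set(float(w) for w in omega_s_grid))

    def width_t(w):
        return min(2.0 * n_cycles / (w * 1e-3), t_extent) if w > 0 else t_extent

    def width_s(w):
        return min(2.0 * n_cycles / abs(w), f_extent) if w != 0 else f_extent

    complex_atoms = []
    for wt in omega_t_grid:
        for ws in omega_s_grid:
            orientations = [ws]
            if include_negative_spectral and wt > 0 and ws > 0:
                orientations.append(-ws)
            for ws_o in orientations:
                complex_atoms.append(
                    gabor_atom(
                        wt,
                        ws_o,
                        width_t(wt),
                        width_s(ws_o),
                        shape=(n_channels, n_frames),
                        frame_period_ms=dt_ms,
                        channel_spacing_bark=df_bark,
                    )
                )

    atoms = []
    for c in complex_atoms:
        atoms.append(realize(c, "real", zero_mean=zero_mean))
        if not c.is_dc:  # imaginary part of the DC atom is identically zero
            atoms.append(realize(c, "imag", zero_mean=zero_mean))

    return GaborBank(
        atoms=atoms,
        complex_atoms=complex_atoms,
        frame_period_ms=dt_ms,
        channel_spacing_bark=df_bark,
        max_temporal_mod=max_temporal_mod,
        max_spectral_mod=max_spectral_mod,
        grid={
            "omega_t": list(omega_t_grid),
            "omega_s": list(omega_s_grid),
            "n_cycles": n_cycles,
            "include_negative_spectral": include_negative_spectral,
        },
    )
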