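"""Free-energy surfaces of the dimer rise: WHAM and Boltzmann inversion.

Reconstructs 1D potentials of mean force from umbrella-sampling windows by
the standard self-consistent weighted-histogram (WHAM) iteration, and 1-3D
free-energy surfaces from unbiased samples by histogramming. Surfaces are
expressed in kBT, referenced to their minimum; unsampled bins are missing
(NaN), never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .constants import DEFAULT_TEMPERATURE, kbt_kj_per_mol
from .lattice import UmbrellaWindow

__all__ = [
    "FreeEnergySurface", "CoverageError", "ConvergenceError",
    "wham", "histogram_fes", "locate_minimum", "compaction_shift",
    "dg_between", "marginalize",
]


class CoverageError(ValueError):
    """A queried position or window chain lies in unsampled territory."""


class ConvergenceError(RuntimeError):
    """WHAM failed to converge within the iteration budget."""


@dataclass
class FreeEnergySurface:
    """Gridded free energy in kBT, min-referenced, NaN where unsampled."""

    edges: list
    G: np.ndarray
    G_err: np.ndarray | None = None
    T: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        self.edges = [np.asarray(e, dtype=float) for e in self.edges]
        self.G = np.asarray(self.G, dtype=float)
        for e in self.edges:
            if np.any(np.diff(e) <= 0):
                raise ValueError("bin edges must be strictly increasing")
        if self.G.shape != tuple(len(e) - 1 for e in self.edges):
            raise ValueError("G shape does not match the bin edges")
        if not np.any(np.isfinite(self.G)):
            raise ValueError("surface has no sampled bins")
        self.G = self.G - np.nanmin(self.G)  # enforce min-reference
        if self.G_err is None:
            self.G_err = np.full_like(self.G, np.nan)
        else:
            self.G_err = np.asarray(self.G_err, dtype=float)
            if self.G_err.shape != self.G.shape:
                raise ValueError("G_err shape mismatch")

    @property
    def dims(self) -> int:
        return len(self.edges)

    @property
    def centers(self) -> list:
        return [(e[:-1] + e[1:]) / 2.0 for e in self.edges]

    def density(self) -> np.ndarray:
        """Normalized probability per bin; missing bins carry zero mass."""
        p = np.exp(-np.nan_to_num(self.G, nan=np.inf))
        return p / p.sum()


def default_rise_edges(lo: float = 7.9, hi: float = 8.7,
                       width: float = 0.005) -> np.ndarray:
    """Default dimer-rise binning: 0.005 nm bins over [7.9, 8.7] nm."""
    return np.arange(lo, hi + width / 2, width)


def _bias_matrix(windows: Sequence[UmbrellaWindow], centers: np.ndarray,
                 T: float) -> np.ndarray:
    """exp(-beta * w_i(x_k)) for harmonic biases given in kJ/mol/nm^2."""
    kbt = kbt_kj_per_mol(T)
    c = np.array([w.center for w in windows])[:, None]
    kb = np.array([w.k_bias for w in windows])[:, None] / kbt  # -> kBT/nm^2
    return np.exp(-0.5 * kb * (centers[None, :] - c) ** 2)


def _wham_solve(counts: np.ndarray, n_i: np.ndarray, bias: np.ndarray,
                tol: float, max_iter: int,
                g_init: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Self-consistent WHAM iteration on binned counts.

    Returns (p, g) with p the unnormalized bin probabilities and g the
    window free energies -ln f_i.
    """
    m_k = counts.sum(axis=0)
    g = np.zeros(len(n_i)) if g_init is None else g_init.copy()
    occupied = m_k > 0
    for it in range(max_iter):
        denom = (n_i[:, None] * np.exp(g)[:, None] * bias).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(occupied & (denom > 0), m_k / denom, 0.0)
        f = bias @ p
        if np.any(f <= 0):
            raise ConvergenceError("window normalization vanished")
        g_new = -np.log(f)
        g_new -= g_new[0]
        delta = np.max(np.abs(g_new - g))
        g = g_new
        if delta < tol:
            return p, g
    raise ConvergenceError(
        f"WHAM did not converge in {max_iter} iterations "
        f"(last max |dg| = {delta:.3e}, tol = {tol:.1e})")


def wham(windows: Sequence[UmbrellaWindow], edges, T: float = DEFAULT_TEMPERATURE,
         tol: float = 1e-8, max_iter: int = 100_000, *,
         n_bootstrap: int = 50, seed: int = 0) -> FreeEnergySurface:
    """Stitch umbrella windows into a 1D PMF by self-consistent WHAM.

    Adjacent windows (ordered by center) must share at least one occupied
    bin, otherwise the profile is disconnected and a :class:`CoverageError`
    is raised. Per-bin uncertainties come from a seeded window-level
    bootstrap (resampling each window's samples with replacement).

    A single window with ``k_bias = 0`` reduces exactly to Boltzmann
    inversion of its histogram.
    """
    if len(windows) == 0:
        raise ValueError("no windows given")
    edges = np.asarray(edges, dtype=float)
    centers = (edges[:-1] + edges[1:]) / 2.0
    order = np.argsort([w.center for w in windows])
    windows = [windows[i] for i in order]

    counts = np.array([np.histogram(w.samples, bins=edges)[0]
                       for w in windows], dtype=float)
    for a, b in zip(counts[:-1], counts[1:]):
        if not np.any((a > 0) & (b > 0)):
            raise CoverageError(
                "adjacent umbrella windows share no occupied bin; "
                "add intermediate windows or widen sampling")
    n_i = counts.sum(axis=1)
    bias = _bias_matrix(windows, centers, T)

    p, g = _wham_solve(counts, n_i, bias, tol, max_iter)
    with np.errstate(divide="ignore"):
        G = np.where(p > 0, -np.log(np.where(p > 0, p, 1.0)), np.nan)

    g_err = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        boot = np.full((n_bootstrap, len(centers)), np.nan)
        for b in range(n_bootstrap):
            bcounts = np.array([
                np.histogram(rng.choice(w.samples, size=w.samples.size,
                                        replace=True), bins=edges)[0]
                for w in windows], dtype=float)
            try:
                pb, _ = _wham_solve(bcounts, bcounts.sum(axis=1), bias,
                                    tol, max_iter, g_init=g)
            except (ConvergenceError, CoverageError):
                continue
            with np.errstate(divide="ignore"):
                Gb = np.where(pb > 0, -np.log(np.where(pb > 0, pb, 1.0)), np.nan)
            boot[b] = Gb - np.nanmin(Gb)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            g_err = np.nanstd(boot, axis=0)
    return FreeEnergySurface(edges=[edges], G=G, G_err=g_err, T=T)


def histogram_fes(samples, edges, T: float = DEFAULT_TEMPERATURE) -> FreeEnergySurface:
    """Free-energy surface by Boltzmann inversion of unbiased samples.

    ``samples`` is (n,) for 1D or (n, d) for d-dimensional surfaces;
    ``edges`` is one edge array per dimension. Empty bins are missing
    (NaN); per-bin errors are the Poisson estimate 1/sqrt(count) in kBT.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if np.isscalar(edges[0]):  # a single edge array was passed
        edges = [np.asarray(edges, dtype=float)]
    else:
        edges = [np.asarray(e, dtype=float) for e in edges]
    if len(edges) != x.shape[1]:
        raise ValueError("one edge array per sample dimension is required")
    counts, _ = np.histogramdd(x, bins=edges)
    if counts.sum() == 0:
        raise ValueError("no samples fall inside the binning range")
    with np.errstate(divide="ignore"):
        G = np.where(counts > 0, -np.log(np.where(counts > 0, counts, 1.0)),
                     np.nan)
        G_err = np.where(counts > 0,
                         1.0 / np.sqrt(np.where(counts > 0, counts, 1.0)),
                         np.nan)
    return FreeEnergySurface(edges=edges, G=G, G_err=G_err, T=T)


def locate_minimum(fes: FreeEnergySurface, *, return_info: bool = False):
    """Grid argmin refined by per-dimension 3-point quadratic interpolation.

    Ties break deterministically toward the lowest coordinate; a tie or
    additional equal minimum sets the ``multimodal`` flag. When the argmin
    sits on the domain boundary (or next to a missing bin) that dimension
    is not refined and a warning is issued.
    """
    G = fes.G
    flat = np.nanargmin(G)
    idx = np.unravel_index(flat, G.shape)
    n_min = int(np.sum(np.isclose(G, G[idx], atol=1e-12, rtol=0.0)))
    multimodal = n_min > 1
    pos = []
    centers = fes.centers
    for ax, i in enumerate(idx):
        c = centers[ax]
        if i == 0 or i == len(c) - 1:
            warnings.warn(f"minimum on boundary of axis {ax}; not refined")
            pos.append(c[i])
            continue
        lo = list(idx); hi = list(idx)
        lo[ax] -= 1; hi[ax] += 1
        g_m, g_0, g_p = G[tuple(lo)], G[idx], G[tuple(hi)]
        if not (np.isfinite(g_m) and np.isfinite(g_p)):
            warnings.warn(f"minimum next to unsampled bin on axis {ax}")
            pos.append(c[i])
            continue
        denom = g_m - 2 * g_0 + g_p
        h = c[1] - c[0]
        # sub-bin refinement, clamped to the argmin bin
        off = 0.5 * h * (g_m - g_p) / denom if denom > 0 else 0.0
        pos.append(c[i] + float(np.clip(off, -h / 2, h / 2)))
    pos = np.array(pos)
    if return_info:
        return pos, {"multimodal": multimodal, "index": idx}
    return pos


def marginalize(fes: FreeEnergySurface, axis: int) -> FreeEnergySurface:
    """Boltzmann-weighted reduction of a surface to one of its axes."""
    if not 0 <= axis < fes.dims:
        raise ValueError("axis out of range")
    p = np.exp(-np.nan_to_num(fes.G, nan=np.inf))
    other = tuple(i for i in range(fes.dims) if i != axis)
    p1 = p.sum(axis=other)
    with np.errstate(divide="ignore"):
        G1 = np.where(p1 > 0, -np.log(np.where(p1 > 0, p1, 1.0)), np.nan)
    return FreeEnergySurface(edges=[fes.edges[axis]], G=G1, T=fes.T)


def compaction_shift(fes_a: FreeEnergySurface, fes_b: FreeEnergySurface, *,
                     samples_a=None, samples_b=None, n_bootstrap: int = 50,
                     seed: int = 0) -> tuple[float, float]:
    """Minimum-position difference a - b (nm) with uncertainty.

    For 2D surfaces each is first reduced per dimension and the per-axis
    shifts averaged. The sd comes from a seeded bootstrap over the raw
    samples when provided, else half a bin width is reported.
    """
    if fes_a.dims != fes_b.dims:
        raise ValueError("surfaces must share dimensionality")

    def _shift(fa, fb):
        if fa.dims == 1:
            return locate_minimum(fa)[0] - locate_minimum(fb)[0]
        return float(np.mean([
            locate_minimum(marginalize(fa, ax))[0]
            - locate_minimum(marginalize(fb, ax))[0]
            for ax in range(fa.dims)]))

    shift = _shift(fes_a, fes_b)
    if samples_a is not None and samples_b is not None:
        rng = np.random.default_rng(seed)
        sa = np.asarray(samples_a, dtype=float)
        sb = np.asarray(samples_b, dtype=float)
        vals = []
        for _ in range(n_bootstrap):
            ra = sa[rng.integers(0, len(sa), len(sa))]
            rb = sb[rng.integers(0, len(sb), len(sb))]
            fa = histogram_fes(ra, fes_a.edges, fes_a.T)
            fb = histogram_fes(rb, fes_b.edges, fes_b.T)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vals.append(_shift(fa, fb))
        sd = float(np.std(vals, ddof=1))
    else:
        sd = float(fes_a.edges[0][1] - fes_a.edges[0][0]) / 2.0
    return float(shift), sd


def _interp(fes: FreeEnergySurface, values: np.ndarray, point) -> float:
    interp = RegularGridInterpolator(fes.centers, values, method="linear",
                                     bounds_error=False, fill_value=np.nan)
    return float(interp(np.atleast_2d(point))[0])


def dg_between(fes: FreeEnergySurface, p_from, p_to) -> tuple[float, float]:
    """Free-energy difference G(p_to) - G(p_from) in kBT, with error.

    Values are multilinearly interpolated between bin centers; querying a
    position whose interpolation stencil touches unsampled bins raises a
    :class:`CoverageError`. The error combines the interpolated per-bin
    uncertainties in quadrature (NaN if the surface carries none).
    """
    g_from = _interp(fes, fes.G, p_from)
    g_to = _interp(fes, fes.G, p_to)
    if not (np.isfinite(g_from) and np.isfinite(g_to)):
        raise CoverageError("queried position lies in unsampled territory")
    e_from = _interp(fes, fes.G_err, p_from)
    e_to = _interp(fes, fes.G_err, p_to)
    err = float(np.sqrt(e_from**2 + e_to**2))
    return g_to - g_from, err
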