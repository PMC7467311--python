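"""Stress-strain analysis of axially loaded protofilaments.

Converts pressure-tensor and box time series into axial stress/strain
points with block-averaged uncertainties and fits regime-wise elastic
moduli. Sign convention: sigma_zz > 0 is extension, sigma_zz < 0 is
compression (an excess of P_zz over the lateral pressure compresses the
filament, hence the leading minus sign in the stress definition).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm

from .constants import A_Z_NM2, BAR_TO_PA
from .lattice import RiseTrajectory

__all__ = [
    "StressStrainPoint", "ElasticFit",
    "block_stats", "axial_stress", "axial_strain",
    "trajectory_point", "fit_modulus",
]

REGIMES = ("extension", "compression", "combined")


@dataclass(frozen=True)
class StressStrainPoint:
    """One (strain, stress) observation with block-averaged errors."""

    sigma_zz: float       # Pa
    sigma_sd: float
    eps_zz: float         # dimensionless
    eps_sd: float
    regime: str

    def __post_init__(self):
        if self.sigma_sd < 0 or self.eps_sd < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass(frozen=True)
class ElasticFit:
    """Fitted elastic modulus for one stress regime."""

    E: float              # GPa
    E_sd: float
    regime: str
    intercept: float      # Pa
    n_points: int


def block_stats(series, n_blocks: int = 5) -> tuple[float, float]:
    """Mean and block-averaged standard error of a correlated series.

    The series is split into ``n_blocks`` contiguous blocks; the error is
    the standard deviation of the block means divided by sqrt(n_blocks).
    """
    x = np.asarray(series, dtype=float).ravel()
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    if x.size < n_blocks:
        raise ValueError("series shorter than the number of blocks")
    blocks = np.array_split(x, n_blocks)
    means = np.array([b.mean() for b in blocks])
    se = means.std(ddof=1) / np.sqrt(n_blocks)
    return float(x.mean()), float(se)


def axial_stress(P_zz, P_xx, P_yy, L_x, L_y, A_z: float = A_Z_NM2,
                 n_pf: int = 1):
    """Axial stress sigma_zz in Pa from pressures (bar) and box (nm).

    sigma_zz = -(P_zz - (P_xx + P_yy)/2) * L_x * L_y / (n_pf * A_z).
    For multi-PF boxes the pressure-derived force is shared equally among
    the ``n_pf`` filaments (reduces to the single-PF definition at n_pf=1).
    """
    if A_z <= 0:
        raise ValueError("A_z must be positive")
    p_perp = (np.asarray(P_xx, dtype=float) + np.asarray(P_yy, dtype=float)) / 2.0
    dp_pa = (np.asarray(P_zz, dtype=float) - p_perp) * BAR_TO_PA
    return -dp_pa * np.asarray(L_x, dtype=float) * np.asarray(L_y, dtype=float) \
        / (n_pf * A_z)


def axial_strain(L_z, L_z_eq: float):
    """Engineering strain (L_z - L_z_eq) / L_z_eq."""
    if L_z_eq <= 0:
        raise ValueError("L_z_eq must be positive")
    return (np.asarray(L_z, dtype=float) - L_z_eq) / L_z_eq


def trajectory_point(traj: RiseTrajectory, L_z_eq: float, *,
                     A_z: float = A_Z_NM2, n_blocks: int = 5,
                     tail_fraction: float = 0.2) -> StressStrainPoint:
    """Reduce one loaded trajectory to a stress-strain point.

    Only the trailing ``tail_fraction`` of the frames enters (the analysis
    window after the system has relaxed under load); means and errors come
    from block averaging with ``n_blocks`` blocks.
    """
    if not 0 < tail_fraction <= 1:
        raise ValueError("tail_fraction must be in (0, 1]")
    n0 = int(traj.n_frames * (1 - tail_fraction))
    sl = slice(n0, None)
    sigma = axial_stress(traj.pressure["P_zz"][sl], traj.pressure["P_xx"][sl],
                         traj.pressure["P_yy"][sl], traj.box["L_x"][sl],
                         traj.box["L_y"][sl], A_z, n_pf=traj.n_pf)
    eps = axial_strain(traj.box["L_z"][sl], L_z_eq)
    s_mean, s_sd = block_stats(sigma, n_blocks)
    e_mean, e_sd = block_stats(eps, n_blocks)
    regime = "extension" if s_mean > 0 else "compression"
    return StressStrainPoint(sigma_zz=s_mean, sigma_sd=s_sd,
                             eps_zz=e_mean, eps_sd=e_sd, regime=regime)


def fit_modulus(points: Sequence[StressStrainPoint], regime: str) -> ElasticFit:
    """Weighted linear fit sigma = E * eps + b over one stress regime.

    Weights are 1/sd^2 of the stress; the fit falls back to ordinary least
    squares when any point carries zero error. E and its standard
    deviation come from the slope and its fit covariance.
    """
    if regime not in REGIMES:
        raise ValueError(f"regime must be one of {REGIMES}")
    sel = [p for p in points
           if regime == "combined" or p.regime == regime]
    if len(sel) < 3:
        raise ValueError(f"need >= 3 points in regime {regime!r}, "
                         f"got {len(sel)}")
    eps = np.array([p.eps_zz for p in sel])
    sig = np.array([p.sigma_zz for p in sel])
    sds = np.array([p.sigma_sd for p in sel])
    X = sm.add_constant(eps)
    if np.any(sds == 0):
        res = sm.OLS(sig, X).fit()
    else:
        res = sm.WLS(sig, X, weights=1.0 / sds**2).fit()
    slope, slope_sd = res.params[1], res.bse[1]
    return ElasticFit(E=float(slope) / 1e9, E_sd=float(slope_sd) / 1e9,
                      regime=regime, intercept=float(res.params[0]),
                      n_points=len(sel))
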