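"""Thermodynamic cycle for lateral-bond stability under compaction mismatch.

Combines the single-PF 1D potentials of mean force with the double-PF 2D
free-energy surface into a map of the relative lateral association free
energy

    ddG_assoc(r1, r2) = [G_d(r1, r2) - G_d(eq)]
                        - [G_s1(r1) - G_s1(eq)] - [G_s2(r2) - G_s2(eq)]

Because the cycle must close, the vertical (compaction) legs alone fix the
horizontal (association) difference: a positive ddG_assoc means lateral
association is less favorable when the two PFs are driven into conflicting
compaction states. ``exp(ddG)`` is the equilibrium-constant fold-change.
The absolute association free energies are never computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .free_energy import FreeEnergySurface, locate_minimum

__all__ = ["CycleResult", "ddg_assoc_map", "fold_change"]


@dataclass
class CycleResult:
    """Mismatch-stability map plus the scalar evaluation point."""

    edges: list                 # 2D grid edges (rise1, rise2), nm
    ddg_map: np.ndarray         # kBT, NaN where the double surface is unsampled
    ddg_err: np.ndarray         # per-bin error, quadrature propagation
    ddg_at: float               # kBT at the evaluation state pair
    ddg_at_err: float
    at_point: tuple[float, float]
    fold_change: float          # exp(ddg_at)


def _interp_1d(centers: np.ndarray, values: np.ndarray,
               x: np.ndarray) -> np.ndarray:
    out = np.interp(x, centers, values, left=np.nan, right=np.nan)
    # propagate missingness: nearest source bin NaN -> NaN
    nan_src = ~np.isfinite(values)
    if nan_src.any():
        idx = np.searchsorted(centers, x).clip(1, len(centers) - 1)
        bad = nan_src[idx] | nan_src[idx - 1]
        out = np.where(bad, np.nan, out)
    return out


def ddg_assoc_map(fes_double: FreeEnergySurface,
                  fes_single_1: FreeEnergySurface,
                  fes_single_2: FreeEnergySurface, *,
                  at_point: tuple[float, float] | None = None) -> CycleResult:
    """Relative lateral-bond stability over the (rise1, rise2) plane.

    All three inputs must be min-referenced surfaces (enforced by
    :class:`FreeEnergySurface`), so the equilibrium legs of the cycle are
    zero by construction and the map is simply G_d - G_s1 - G_s2 on the
    double-PF grid. Errors are combined in quadrature. The scalar
    ``ddg_at`` defaults to the sampled bin maximizing the rise mismatch
    |r1 - r2| (override with ``at_point``).
    """
    if fes_double.dims != 2:
        raise ValueError("fes_double must be 2D")
    if fes_single_1.dims != 1 or fes_single_2.dims != 1:
        raise ValueError("single-PF surfaces must be 1D")
    c1, c2 = fes_double.centers
    g1 = _interp_1d(fes_single_1.centers[0], fes_single_1.G, c1)
    g2 = _interp_1d(fes_single_2.centers[0], fes_single_2.G, c2)
    e1 = _interp_1d(fes_single_1.centers[0], fes_single_1.G_err, c1)
    e2 = _interp_1d(fes_single_2.centers[0], fes_single_2.G_err, c2)

    ddg = fes_double.G - g1[:, None] - g2[None, :]
    err = np.sqrt(fes_double.G_err**2 + e1[:, None]**2 + e2[None, :]**2)

    sampled = np.isfinite(ddg)
    if not sampled.any():
        raise ValueError("no overlap between double- and single-PF domains")
    if at_point is None:
        mismatch = np.abs(c1[:, None] - c2[None, :])
        mismatch = np.where(sampled, mismatch, -np.inf)
        i, j = np.unravel_index(np.argmax(mismatch), mismatch.shape)
        at_point = (float(c1[i]), float(c2[j]))
    else:
        i = int(np.argmin(np.abs(c1 - at_point[0])))
        j = int(np.argmin(np.abs(c2 - at_point[1])))
        if not sampled[i, j]:
            raise ValueError("requested evaluation point is unsampled")
    ddg_at = float(ddg[i, j])
    ddg_at_err = float(err[i, j])
    return CycleResult(edges=fes_double.edges, ddg_map=ddg, ddg_err=err,
                       ddg_at=ddg_at, ddg_at_err=ddg_at_err,
                       at_point=at_point, fold_change=fold_change(ddg_at))


def fold_change(ddg: float) -> float:
    """Equilibrium-constant fold-change exp(ddG) for ddG in kBT."""
    if not np.isfinite(ddg):
        raise ValueError("ddg must be finite")
    return float(np.exp(ddg))
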