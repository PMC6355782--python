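"""Entropy/enthalpy decomposition of pair free-energy profiles.

The temperature dependence of the potential of mean force splits dG into an
entropic part, -T dS = T (dG/dT), estimated by a central finite difference
from profiles at T - dT and T + dT, and an enthalpic part dH = dG + T dS.
The central difference is exact for G affine in T, and the closure
(-T dS) + dH = dG holds bin-wise by construction wherever all inputs are
defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Trajectory
from .pairs import FreeEnergyProfile, MinimaReport, com_rdf, \
    free_energy_profile, locate_minima

__all__ = ["ThermoDecomposition", "entropic_component",
           "enthalpic_component", "decompose"]

DEFAULT_TEMPERATURES = (283.0, 298.0, 313.0)


@dataclass
class ThermoDecomposition:
    """Per-distance free energy and its entropic/enthalpic components."""

    r_grid: np.ndarray
    dG: np.ndarray             # at the central temperature, kJ/mol
    minus_TdS: np.ndarray      # kJ/mol
    dH: np.ndarray             # kJ/mol
    defined: np.ndarray
    temperature: float         # central T, K
    delta_T: float             # K
    minima: MinimaReport | None = None
    minima_minus_TdS: tuple | None = None   # values at (min1, min2)
    minima_dH: tuple | None = None


def _check_grids(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape or not np.allclose(a, b, rtol=0, atol=1e-9):
        raise ValueError("free-energy profiles must share an identical r-grid")


def entropic_component(fep_lo: FreeEnergyProfile,
                       fep_hi: FreeEnergyProfile,
                       central_T: float) -> tuple[np.ndarray, np.ndarray]:
    """-T dS(r) = (T / 2 dT) (G(T + dT) - G(T - dT)) per bin.

    Returns (minus_TdS, defined); bins undefined in either input profile are
    masked (NaN).
    """
    _check_grids(fep_lo.r_grid, fep_hi.r_grid)
    two_dt = fep_hi.temperature - fep_lo.temperature
    if two_dt <= 0:
        raise ValueError("fep_hi must be the higher-temperature profile")
    mid = 0.5 * (fep_hi.temperature + fep_lo.temperature)
    if abs(mid - central_T) > 1e-6:
        raise ValueError(
            f"central_T {central_T} K is not midway between "
            f"{fep_lo.temperature} and {fep_hi.temperature} K")
    defined = fep_lo.defined & fep_hi.defined
    out = np.full_like(fep_lo.dG, np.nan)
    out[defined] = (central_T / two_dt) * (fep_hi.dG[defined]
                                           - fep_lo.dG[defined])
    return out, defined


def enthalpic_component(fep_central: FreeEnergyProfile,
                        minus_TdS: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """dH(r) = dG(r) - (-T dS(r)) per bin; masks propagate."""
    minus_TdS = np.asarray(minus_TdS, dtype=float)
    if minus_TdS.shape != fep_central.dG.shape:
        raise ValueError("minus_TdS grid does not match the central profile")
    defined = fep_central.defined & np.isfinite(minus_TdS)
    out = np.full_like(fep_central.dG, np.nan)
    out[defined] = fep_central.dG[defined] - minus_TdS[defined]
    return out, defined


def _composition_signature(traj: Trajectory) -> tuple:
    topo = traj.topology
    full = topo.select(group="fullerene")
    return (topo.n_beads, len(full),
            len(np.unique(topo.molecule_id[full])) if len(full) else 0)


def decompose(traj_lo: Trajectory, traj_central: Trajectory,
              traj_hi: Trajectory,
              temperatures: tuple[float, float, float] = DEFAULT_TEMPERATURES,
              **rdf_kwargs) -> ThermoDecomposition:
    """Full decomposition from trajectories at three temperatures.

    The three systems must have identical composition; RDF and Boltzmann
    inversion run with identical settings (same normalization convention and
    plateau window) on a shared r-grid. Values of -T dS and dH at the two
    minima of the central-temperature profile are reported alongside the
    full curves.
    """
    t_lo, t_c, t_hi = temperatures
    if not (t_lo < t_c < t_hi):
        raise ValueError("temperatures must be ordered (lo, central, hi)")
    sig = _composition_signature(traj_central)
    for other, name in ((traj_lo, "low-T"), (traj_hi, "high-T")):
        if _composition_signature(other) != sig:
            raise ValueError(f"{name} trajectory has a different composition "
                             "than the central one")
    feps = []
    for traj, temp in ((traj_lo, t_lo), (traj_central, t_c), (traj_hi, t_hi)):
        pd = com_rdf(traj, **rdf_kwargs)
        feps.append(free_energy_profile(pd, temp))
    fep_lo, fep_c, fep_hi = feps
    _check_grids(fep_lo.r_grid, fep_c.r_grid)

    minus_tds, def_s = entropic_component(fep_lo, fep_hi, t_c)
    dh, def_h = enthalpic_component(fep_c, minus_tds)
    defined = def_s & def_h

    minima = minima_s = minima_h = None
    try:
        minima = locate_minima(fep_c)
        dr = fep_c.r_grid[1] - fep_c.r_grid[0]
        idx = [int(np.clip(round((r - fep_c.r_grid[0]) / dr), 0,
                           len(fep_c.r_grid) - 1))
               for r in (minima.r_min1, minima.r_min2)]
        minima_s = tuple(float(minus_tds[i]) for i in idx)
        minima_h = tuple(float(dh[i]) for i in idx)
    except ValueError:
        pass  # sparse sampling: full curves are still reported

    return ThermoDecomposition(
        r_grid=fep_c.r_grid, dG=fep_c.dG, minus_TdS=minus_tds, dH=dh,
        defined=defined, temperature=t_c, delta_T=(t_hi - t_lo) / 2,
        minima=minima, minima_minus_TdS=minima_s, minima_dH=minima_h)
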