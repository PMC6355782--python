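"""Membrane dimension observables: APL, VPL, thickness, density profiles,
and the isothermal area compressibility from box-area fluctuations."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .constants import KB, KJ_PER_MOL_NM2_TO_MN_PER_M
from .core import LIPID_GROUPS, Trajectory, center_of_mass

__all__ = [
    "SeriesSummary",
    "MembraneProfile",
    "MembraneDimensions",
    "area_per_lipid",
    "volume_per_lipid",
    "density_profile",
    "bilayer_thickness",
    "area_compressibility",
]


@dataclass
class SeriesSummary:
    """Per-frame values with their mean and standard deviation."""

    values: np.ndarray
    mean: float
    sd: float

    @classmethod
    def from_values(cls, values: np.ndarray) -> "SeriesSummary":
        values = np.asarray(values, dtype=float)
        return cls(values=values, mean=float(values.mean()),
                   sd=float(values.std(ddof=1)) if len(values) > 1 else 0.0)


@dataclass
class MembraneProfile:
    """Mass density along the bilayer normal, per bead group.

    ``z_grid`` holds bin centres (nm) relative to the per-frame lipid centre
    of mass, symmetric about 0; ``density`` maps group label -> amu/nm^3.
    """

    z_grid: np.ndarray
    density: Mapping[str, np.ndarray]
    bin_width: float
    n_frames: int
    box_area: float  # mean in-plane box area, nm^2


@dataclass
class MembraneDimensions:
    apl: SeriesSummary
    vpl: SeriesSummary | None
    thickness: float
    ka: float | None = None
    ka_err: float | None = None


def area_per_lipid(traj: Trajectory) -> SeriesSummary:
    """Per-frame area per lipid, Lx*Ly / (n_lipids / 2), in nm^2."""
    n_lipids = traj.topology.n_lipids
    if n_lipids == 0:
        raise ValueError("no lipids in topology")
    areas = traj.boxes[:, 0] * traj.boxes[:, 1]
    return SeriesSummary.from_values(areas / (n_lipids / 2))


def volume_per_lipid(traj: Trajectory, water_bead_volume: float,
                     particle_volume: float = 0.0) -> SeriesSummary:
    """Per-frame volume per lipid in nm^3.

    VPL = (V_box - N_water * water_bead_volume - N_particles *
    particle_volume) / n_lipids. With the default ``particle_volume`` of 0
    the result is the lipid + nanoparticle composite volume; pass a
    calibrated per-particle volume to remove the nanoparticle contribution.
    """
    if water_bead_volume <= 0:
        raise ValueError("water_bead_volume must be positive")
    topo = traj.topology
    n_lipids = topo.n_lipids
    if n_lipids == 0:
        raise ValueError("no lipids in topology")
    n_water = len(np.unique(topo.molecule_id[topo.select(group="water")]))
    full = topo.select(group="fullerene")
    n_part = len(np.unique(topo.molecule_id[full])) if len(full) else 0
    v_box = traj.boxes.prod(axis=1)
    vpl = (v_box - n_water * water_bead_volume
           - n_part * particle_volume) / n_lipids
    if np.any(vpl <= 0):
        raise ValueError(
            "negative volume per lipid; water_bead_volume miscalibrated?")
    return SeriesSummary.from_values(vpl)


def _lipid_com_z(traj: Trajectory, i: int) -> float:
    idx = traj.topology.select(group=LIPID_GROUPS)
    if len(idx) == 0:
        idx = np.arange(traj.n_beads)
    com = center_of_mass(traj.coords[i, idx], traj.topology.mass[idx],
                         box=traj.boxes[i], pbc=True)
    return float(com[2])


def density_profile(traj: Trajectory,
                    groups: Sequence[str],
                    bin_width: float = 0.1,
                    z_max: float | None = None) -> MembraneProfile:
    """Frame-averaged mass density profiles along z, per group (amu/nm^3).

    z is measured relative to the lipid-bead centre of mass of each frame
    (minimum-image), binned symmetrically about 0 and divided by the bin
    volume Lx*Ly*bin_width of that frame.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if traj.n_frames < 1:
        raise ValueError("empty trajectory")
    topo = traj.topology
    selections = {}
    for g in groups:
        idx = topo.select(group=g)
        if len(idx) == 0:
            raise ValueError(f"no beads in group {g!r}")
        selections[g] = idx

    if z_max is None:
        z_max = traj.boxes[:, 2].max() / 2
    n_half = int(np.ceil(z_max / bin_width))
    edges = np.arange(-n_half, n_half + 1) * bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])

    acc = {g: np.zeros(len(centers)) for g in groups}
    for i in range(traj.n_frames):
        z0 = _lipid_com_z(traj, i)
        lz = traj.boxes[i, 2]
        area = traj.boxes[i, 0] * traj.boxes[i, 1]
        for g, idx in selections.items():
            dz = traj.coords[i, idx, 2] - z0
            dz -= lz * np.round(dz / lz)  # minimum image along z
            hist, _ = np.histogram(dz, bins=edges,
                                   weights=topo.mass[idx])
            acc[g] += hist / (area * bin_width)
    density = {g: acc[g] / traj.n_frames for g in groups}
    mean_area = float((traj.boxes[:, 0] * traj.boxes[:, 1]).mean())
    return MembraneProfile(z_grid=centers, density=density,
                           bin_width=bin_width, n_frames=traj.n_frames,
                           box_area=mean_area)


def _refine_peak(z: np.ndarray, y: np.ndarray, i: int) -> float:
    """Quadratic (3-point) interpolation through a maximum bin."""
    if i == 0 or i == len(y) - 1:
        return float(z[i])
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom >= 0 or abs(denom) < 1e-300:
        return float(z[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(z[i] + delta * (z[1] - z[0]))


def bilayer_thickness(profile: MembraneProfile,
                      head_group: str = "lipid_head") -> float:
    """Head-peak-to-head-peak distance (nm) across the bilayer midplane.

    Each leaflet's head-density maximum is refined by quadratic interpolation
    through the maximum bin and its neighbours.
    """
    if head_group not in profile.density:
        raise ValueError(f"profile lacks group {head_group!r}")
    z = profile.z_grid
    y = np.asarray(profile.density[head_group], dtype=float)
    lo = np.flatnonzero(z < 0)
    hi = np.flatnonzero(z > 0)
    if len(lo) == 0 or len(hi) == 0 or y[lo].max() == 0 or y[hi].max() == 0:
        raise ValueError("no bilayer structure: need a head-density peak on "
                         "each side of the midplane")
    i_lo = lo[np.argmax(y[lo])]
    i_hi = hi[np.argmax(y[hi])]
    z_lo = _refine_peak(z, y, i_lo)
    z_hi = _refine_peak(z, y, i_hi)
    if z_hi <= z_lo:
        raise ValueError("no bilayer structure: head peaks not separated")
    return z_hi - z_lo


def area_compressibility(area_series: np.ndarray, temperature: float,
                         n_blocks: int = 5,
                         as_mn_per_m: bool = False) -> tuple[float, float]:
    """Isothermal area compressibility modulus K_A from area fluctuations.

    K_A = kB T <A> / Var(A), with A the total box area (nm^2). Returns
    (K_A, uncertainty) in kJ/(mol nm^2), or mN/m with ``as_mn_per_m``.
    Uncertainty is the standard error of per-block estimates (block
    averaging, default 5 blocks).
    """
    a = np.asarray(area_series, dtype=float)
    if len(a) < 100:
        raise ValueError("need >= 100 frames for a fluctuation estimate")
    var = a.var(ddof=1)
    if var == 0:
        raise ValueError("rigid area -- barostat off?")
    ka = KB * temperature * a.mean() / var

    blocks = np.array_split(a, n_blocks)
    vals = []
    for b in blocks:
        v = b.var(ddof=1)
        if v > 0:
            vals.append(KB * temperature * b.mean() / v)
    vals = np.asarray(vals)
    err = (vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.inf
    if as_mn_per_m:
        ka *= KJ_PER_MOL_NM2_TO_MN_PER_M
        err *= KJ_PER_MOL_NM2_TO_MN_PER_M
    return float(ka), float(err)
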