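"""Pair structure of the nanoparticle phase.

Centre-of-mass radial distribution functions in thin-film geometry (three
normalization conventions, declared in every result), Boltzmann-inversion
free-energy profiles dG(r) = -kB T ln g(r), minima location with sub-bin
quadratic refinement, detection of a split second coordination shell (the
short-range-order signature), and the in-plane density of beads along the
axis connecting nanoparticle pairs at a chosen separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.signal import find_peaks

from .constants import KB
from .core import LIPID_GROUPS, Trajectory, minimum_image_displacement
from .aggregation import fullerene_com_series, fullerene_coms

__all__ = [
    "PairDistribution", "FreeEnergyProfile", "MinimaReport",
    "com_rdf", "free_energy_profile", "locate_minima",
    "detect_second_peak_split", "pair_axis_density", "PairAxisDensity",
]

MODES = ("raw_histogram", "shell_normalized", "plateau_normalized")


@dataclass
class PairDistribution:
    """Binned centre-of-mass pair distances.

    ``mode`` records the normalization convention:
    raw_histogram — accumulated pair counts;
    shell_normalized — counts / (n_frames * n_pairs * 4 pi r^2 dr / V);
    plateau_normalized — counts divided by their mean over the plateau
    window (the thin-film convention: no ideal-gas shell volume assumed).
    """

    r_grid: np.ndarray
    g: np.ndarray
    mode: str
    pair_count: int
    n_frames: int
    bin_width: float
    counts: np.ndarray = field(repr=False, default=None)
    plateau_window: tuple | None = None


@dataclass
class FreeEnergyProfile:
    """Boltzmann inversion of a pair distribution at one temperature.

    ``dG`` is NaN (and ``defined`` False) wherever g = 0; the additive
    constant follows the normalization convention recorded in ``reference``.
    """

    r_grid: np.ndarray
    dG: np.ndarray
    defined: np.ndarray
    temperature: float
    reference: str


@dataclass
class MinimaReport:
    """Contact (first) and solvent-separated (second) free-energy minima."""

    r_min1: float
    dG_min1: float
    r_min2: float
    dG_min2: float

    @property
    def ddG(self) -> float:
        """dG_min1 - dG_min2; negative means the contact pair is favoured."""
        return self.dG_min1 - self.dG_min2


def com_rdf(traj: Trajectory,
            bin_width: float = 0.02,
            r_max: float | None = None,
            mode: str = "plateau_normalized",
            plateau_window: tuple[float, float] = (2.5, 3.2),
            window_fraction: float = 0.5) -> PairDistribution:
    """Fullerene-fullerene centre-of-mass RDF over the analysis window.

    Distances are 3D minimum-image. ``r_max`` defaults to
    min(half smallest box edge, 3.5 nm) and must stay below the half box.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    sub = traj.analysis_window(window_fraction)
    half_box = sub.boxes.min() / 2
    if r_max is None:
        r_max = min(half_box * 0.999, 3.5)
    if r_max >= half_box:
        raise ValueError(f"r_max {r_max} >= half the smallest box edge "
                         f"{half_box}")
    edges = np.arange(0, r_max + bin_width / 2, bin_width)
    if edges[-1] < r_max:
        edges = np.append(edges, edges[-1] + bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])

    coms_all = fullerene_com_series(sub)  # (F, M, 3)
    n_mol = coms_all.shape[1]
    if n_mol < 2:
        raise ValueError("need >= 2 fullerene molecules for an RDF")
    iu, ju = np.triu_indices(n_mol, 1)
    n_pairs_frame = len(iu)
    counts = np.zeros(len(centers))
    chunk = max(1, 4_000_000 // max(1, n_pairs_frame))
    for lo_f in range(0, sub.n_frames, chunk):
        c = coms_all[lo_f:lo_f + chunk]
        b = sub.boxes[lo_f:lo_f + chunk, None, :]
        d = c[:, iu, :] - c[:, ju, :]
        d -= b * np.round(d / b)
        r = np.sqrt((d**2).sum(-1)).ravel()
        h, _ = np.histogram(r, bins=edges)
        counts += h
    vols = sub.boxes.prod(axis=1)

    total_pairs = int(counts.sum())
    if mode == "raw_histogram":
        g = counts.copy()
    elif mode == "shell_normalized":
        v_mean = float(np.mean(vols))
        shell = 4 * np.pi * centers**2 * bin_width
        ideal = sub.n_frames * n_pairs_frame * shell / v_mean
        g = counts / ideal
    else:
        lo, hi = plateau_window
        sel = (centers >= lo) & (centers <= hi)
        if not sel.any():
            raise ValueError(f"plateau window {plateau_window} contains no "
                             f"bins (r_max {r_max})")
        ref = counts[sel].mean()
        if ref == 0:
            raise ValueError("no pair counts in the plateau window; widen "
                             "it or sample longer")
        g = counts / ref
    return PairDistribution(r_grid=centers, g=g, mode=mode,
                            pair_count=total_pairs, n_frames=sub.n_frames,
                            bin_width=bin_width, counts=counts,
                            plateau_window=(tuple(plateau_window)
                                            if mode == "plateau_normalized"
                                            else None))


def free_energy_profile(pd: PairDistribution,
                        temperature: float) -> FreeEnergyProfile:
    """dG(r) = -kB T ln g(r); bins with g = 0 are masked, never +/-inf."""
    if pd.mode == "raw_histogram":
        raise ValueError(
            "raw_histogram mode carries an undefined additive constant; "
            "use shell_normalized or plateau_normalized")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    g = np.asarray(pd.g, dtype=float)
    defined = g > 0
    dG = np.full_like(g, np.nan)
    dG[defined] = -KB * temperature * np.log(g[defined])
    ref = (f"g normalized by {pd.mode}"
           + (f", plateau window {pd.plateau_window} nm"
              if pd.plateau_window else ""))
    return FreeEnergyProfile(r_grid=pd.r_grid.copy(), dG=dG, defined=defined,
                             temperature=float(temperature), reference=ref)


def _refine_extremum(r: np.ndarray, y: np.ndarray, i: int,
                     defined: np.ndarray) -> tuple[float, float]:
    """Quadratic 3-point refinement of an extremum at bin i."""
    if (0 < i < len(y) - 1 and defined[i - 1] and defined[i + 1]):
        denom = y[i - 1] - 2 * y[i] + y[i + 1]
        if abs(denom) > 1e-300:
            delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
            if abs(delta) <= 1:
                dr = r[1] - r[0]
                r0 = r[i] + delta * dr
                y0 = y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta
                return float(r0), float(y0)
    return float(r[i]), float(y[i])


def locate_minima(fep: FreeEnergyProfile,
                  window1: tuple[float, float] = (0.85, 1.25),
                  window2: tuple[float, float] = (1.30, 1.75)) -> MinimaReport:
    """Locate the contact and solvent-separated minima of dG(r).

    Each minimum is the lowest defined bin inside its search window, refined
    by quadratic interpolation. ddG = dG_min1 - dG_min2 is additive-constant
    free.
    """
    if window1[1] > window2[0]:
        raise ValueError("search windows must be disjoint and ordered")
    out = []
    for lo, hi in (window1, window2):
        sel = np.flatnonzero((fep.r_grid >= lo) & (fep.r_grid <= hi)
                             & fep.defined)
        if len(sel) == 0:
            raise ValueError(f"no defined free-energy bins in [{lo}, {hi}] nm")
        i = sel[np.argmin(fep.dG[sel])]
        out.append(_refine_extremum(fep.r_grid, fep.dG, i, fep.defined))
    (r1, g1), (r2, g2) = out
    return MinimaReport(r_min1=r1, dG_min1=g1, r_min2=r2, dG_min2=g2)


def detect_second_peak_split(pd: PairDistribution,
                             window: tuple[float, float] = (1.30, 2.20),
                             prominence_frac: float = 0.02) -> dict:
    """Detect a split second coordination shell of the RDF.

    split is True iff the window holds >= 2 local maxima, each with
    prominence >= prominence_frac * max g in the window (which entails a
    local minimum between them). Sub-peak positions are refined by quadratic
    interpolation.
    """
    sel = np.flatnonzero((pd.r_grid >= window[0]) & (pd.r_grid <= window[1]))
    if len(sel) < 3:
        raise ValueError(f"window {window} outside or too narrow for the "
                         "r-grid")
    g = np.asarray(pd.g, dtype=float)[sel]
    gmax = g.max()
    if gmax <= 0:
        return {"split": False, "subpeak_positions": []}
    peaks, _ = find_peaks(g, prominence=prominence_frac * gmax)
    defined = np.ones(len(g), dtype=bool)
    positions = [
        _refine_extremum(pd.r_grid[sel], g, int(p), defined)[0]
        for p in peaks
    ]
    return {"split": bool(len(peaks) >= 2),
            "subpeak_positions": positions}


@dataclass
class PairAxisDensity:
    """Linear bead density along the axis joining nanoparticle pairs."""

    axial_grid: np.ndarray           # nm, 0 at the pair midpoint
    density: Mapping[str, np.ndarray]  # beads per nm per pair
    n_pairs: int
    separation: float
    cylinder_radius: float


def pair_axis_density(traj: Trajectory,
                      separation: float,
                      tolerance: float = 0.05,
                      cylinder_radius: float = 0.5,
                      bin_width: float = 0.05,
                      axial_extent: float = 1.5,
                      window_fraction: float = 0.5) -> PairAxisDensity:
    """Density of lipid and fullerene beads along the inter-pair axis.

    Every fullerene COM pair at minimum-image distance within
    ``separation +/- tolerance`` defines a local axis with origin at the pair
    midpoint. Beads within ``cylinder_radius`` of the axis are histogrammed
    by axial coordinate over ``[-axial_extent, axial_extent]``; counts are
    averaged per qualifying pair and divided by the bin width.
    """
    sub = traj.analysis_window(window_fraction)
    topo = sub.topology
    groups = {
        "lipid": topo.select(group=LIPID_GROUPS),
        "fullerene": topo.select(group="fullerene"),
    }
    groups = {k: v for k, v in groups.items() if len(v)}
    n_bins = int(np.ceil(2 * axial_extent / bin_width))
    edges = np.linspace(-axial_extent, axial_extent, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    acc = {k: np.zeros(n_bins) for k in groups}
    n_pairs = 0
    for i in range(sub.n_frames):
        box = sub.boxes[i]
        coms = fullerene_coms(sub, i)
        n = coms.shape[0]
        for a in range(n):
            for b in range(a + 1, n):
                dab = minimum_image_displacement(coms[a], coms[b], box)
                r = np.linalg.norm(dab)
                if abs(r - separation) > tolerance:
                    continue
                n_pairs += 1
                mid = coms[a] + 0.5 * dab
                e = dab / r
                for k, idx in groups.items():
                    rel = minimum_image_displacement(
                        mid, sub.coords[i, idx], box)
                    axial = rel @ e
                    radial = np.linalg.norm(rel - np.outer(axial, e), axis=1)
                    ok = radial < cylinder_radius
                    h, _ = np.histogram(axial[ok], bins=edges)
                    acc[k] += h
    if n_pairs == 0:
        raise ValueError(
            f"no fullerene pairs at separation {separation} +/- {tolerance} "
            f"nm in the {sub.n_frames}-frame analysis window")
    density = {k: acc[k] / (n_pairs * bin_width) for k in groups}
    return PairAxisDensity(axial_grid=centers, density=density,
                           n_pairs=n_pairs, separation=float(separation),
                           cylinder_radius=float(cylinder_radius))
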