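"""Topologies, trajectories and periodic-boundary geometry.

The in-memory model is deliberately small: a :class:`BeadTopology` maps every
bead to a molecule, a group label and a mass; a :class:`Trajectory` holds the
coordinates of all frames as one ``(n_frames, n_beads, 3)`` array in nm
together with per-frame orthorhombic box dimensions and times. Coordinate
input is the GRO dialect (multi-frame concatenation accepted) or XTC, parsed
through mdtraj; the group/species/mass assignment always comes from an
explicit topology-map config, never from guessing bead names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "GROUPS",
    "LIPID_GROUPS",
    "TopologyError",
    "TrajectoryParseError",
    "BeadTopology",
    "Frame",
    "Trajectory",
    "load_topology_map",
    "save_topology_map",
    "read_trajectory",
    "write_trajectory",
    "minimum_image_displacement",
    "minimum_image_distance",
    "center_of_mass",
]

#: Recognised bead group labels.
GROUPS = (
    "lipid_head",
    "lipid_glycerol",
    "lipid_tail",
    "double_bond",
    "fullerene",
    "water",
    "other",
)

#: Groups counted as part of a lipid molecule.
LIPID_GROUPS = ("lipid_head", "lipid_glycerol", "lipid_tail", "double_bond")


class TopologyError(ValueError):
    """Raised for inconsistent or incomplete bead-group assignments."""


class TrajectoryParseError(ValueError):
    """Raised for malformed coordinate input (names the offending frame)."""


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

@dataclass
class BeadTopology:
    """Static per-bead metadata: molecule id, group label, species, mass.

    Beads are 0-indexed internally; 1-based numbering exists only at file
    boundaries. ``molecule_id`` is contiguous (0..n_molecules-1) and
    contiguous per species.
    """

    names: np.ndarray          # bead (atom) names, str
    molecule_id: np.ndarray    # int, 0-based
    group: np.ndarray          # str, one of GROUPS
    species: np.ndarray        # str molecule name (DPPC, F16, W, ...)
    mass: np.ndarray           # amu, > 0

    def __post_init__(self) -> None:
        self.names = np.asarray(self.names, dtype=object)
        self.molecule_id = np.asarray(self.molecule_id, dtype=np.int64)
        self.group = np.asarray(self.group, dtype=object)
        self.species = np.asarray(self.species, dtype=object)
        self.mass = np.asarray(self.mass, dtype=np.float64)
        self.validate()

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        n = len(self.names)
        for arr, what in ((self.molecule_id, "molecule_id"),
                          (self.group, "group"),
                          (self.species, "species"),
                          (self.mass, "mass")):
            if len(arr) != n:
                raise TopologyError(f"{what} length {len(arr)} != {n} beads")
        if n == 0:
            raise TopologyError("empty topology")
        bad = set(self.group) - set(GROUPS)
        if bad:
            raise TopologyError(f"unknown group labels: {sorted(bad)}")
        if np.any(self.mass <= 0):
            raise TopologyError("non-positive bead mass")
        # molecule ids contiguous overall and per species
        uniq = np.unique(self.molecule_id)
        if uniq[0] != 0 or not np.array_equal(uniq, np.arange(len(uniq))):
            raise TopologyError("molecule_ids must be contiguous from 0")
        for sp in np.unique(self.species.astype(str)):
            mids = np.unique(self.molecule_id[self.species == sp])
            if not np.array_equal(mids, np.arange(mids[0], mids[0] + len(mids))):
                raise TopologyError(f"molecule_ids of species {sp!r} not contiguous")
        for mid in uniq:
            if len(set(self.species[self.molecule_id == mid].astype(str))) != 1:
                raise TopologyError(f"molecule {mid} spans multiple species")
        # fullerene molecules must have a uniform bead count per species
        full = np.unique(self.molecule_id[self.group == "fullerene"])
        if len(full):
            counts = {}
            for mid in full:
                sp = str(self.species[self.molecule_id == mid][0])
                counts.setdefault(sp, set()).add(
                    int(np.sum(self.molecule_id == mid)))
            for sp, sizes in counts.items():
                if len(sizes) != 1:
                    raise TopologyError(
                        f"fullerene species {sp!r} has varying bead counts "
                        f"{sorted(sizes)}; each model must have a fixed count")

    # -- queries -----------------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.names)

    @property
    def n_molecules(self) -> int:
        return int(self.molecule_id.max()) + 1

    def select(self, group: str | Sequence[str] | None = None,
               species: str | None = None) -> np.ndarray:
        """Indices of beads matching the given group label(s) and/or species."""
        mask = np.ones(self.n_beads, dtype=bool)
        if group is not None:
            if isinstance(group, str):
                group = (group,)
            mask &= np.isin(self.group.astype(str), list(group))
        if species is not None:
            mask &= self.species.astype(str) == species
        return np.flatnonzero(mask)

    def molecules(self, group: str | None = None) -> list[np.ndarray]:
        """Bead-index arrays per molecule, optionally only molecules that
        contain at least one bead of the given group."""
        out = []
        for mid in range(self.n_molecules):
            idx = np.flatnonzero(self.molecule_id == mid)
            if group is None or np.any(self.group[idx] == group):
                out.append(idx)
        return out

    @property
    def n_lipids(self) -> int:
        lip = self.select(group=LIPID_GROUPS)
        return len(np.unique(self.molecule_id[lip]))


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

@dataclass
class Frame:
    """One snapshot: time (ns), orthorhombic box (nm), N x 3 coords (nm)."""

    time: float
    box: np.ndarray
    coords: np.ndarray
    wrapped: bool = True

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=np.float64)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise TrajectoryParseError(f"non-positive or malformed box {self.box}")
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise TrajectoryParseError("coords must be N x 3")


@dataclass
class Trajectory:
    """Ordered frames sharing one topology.

    Coordinates are stored as a single ``(n_frames, n_beads, 3)`` float array;
    ``boxes`` is ``(n_frames, 3)`` and ``times`` strictly increasing (ns).
    """

    topology: BeadTopology
    coords: np.ndarray
    boxes: np.ndarray
    times: np.ndarray
    wrapped: bool = True
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.boxes = np.asarray(self.boxes, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryParseError("coords must be (n_frames, n_beads, 3)")
        nf, nb, _ = self.coords.shape
        if self.boxes.shape != (nf, 3):
            raise TrajectoryParseError("boxes must be (n_frames, 3)")
        if self.times.shape != (nf,):
            raise TrajectoryParseError("times must be (n_frames,)")
        if nb != self.topology.n_beads:
            raise TrajectoryParseError(
                f"frame bead count {nb} != topology bead count "
                f"{self.topology.n_beads}")
        bad = np.flatnonzero(np.any(self.boxes <= 0, axis=1))
        if len(bad):
            raise TrajectoryParseError(f"non-positive box in frame {bad[0]}")
        if nf > 1 and np.any(np.diff(self.times) <= 0):
            raise TrajectoryParseError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> Frame:
        return Frame(time=float(self.times[i]), box=self.boxes[i],
                     coords=self.coords[i], wrapped=self.wrapped)

    def __iter__(self) -> Iterator[Frame]:
        return (self.frame(i) for i in range(self.n_frames))

    def __len__(self) -> int:
        return self.n_frames

    def slice(self, start: int | None = None, stop: int | None = None,
              step: int | None = None) -> "Trajectory":
        sl = np.s_[start:stop:step]
        return Trajectory(self.topology, self.coords[sl], self.boxes[sl],
                          self.times[sl], wrapped=self.wrapped,
                          metadata=dict(self.metadata))

    def analysis_window(self, fraction: float = 0.5) -> "Trajectory":
        """Trailing fraction of the trajectory used for equilibrium analysis."""
        if not 0 < fraction <= 1:
            raise ValueError("window fraction must be in (0, 1]")
        start = self.n_frames - max(1, int(round(fraction * self.n_frames)))
        return self.slice(start, None)

    def timestep(self) -> float:
        """Uniform frame spacing in ns; raises on non-uniform spacing."""
        if self.n_frames < 2:
            raise ValueError("need >= 2 frames for a timestep")
        dts = np.diff(self.times)
        if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-12):
            raise ValueError("non-uniform frame spacing")
        return float(dts[0])


# ---------------------------------------------------------------------------
# topology-map config
# ---------------------------------------------------------------------------

def load_topology_map(path: str | Path) -> dict:
    """Read a bead-name -> {group, species, mass} mapping from YAML.

    Schema::

        beads:
          NC3: {group: lipid_head, species: DPPC, mass: 72.0}
          ...
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping) or "beads" not in data:
        raise TopologyError(f"{path}: topology map must have a 'beads' section")
    beads = data["beads"]
    for name, entry in beads.items():
        for key in ("group", "species", "mass"):
            if key not in entry:
                raise TopologyError(f"{path}: bead {name!r} missing {key!r}")
        if entry["group"] not in GROUPS:
            raise TopologyError(
                f"{path}: bead {name!r} has unknown group {entry['group']!r}")
        if float(entry["mass"]) <= 0:
            raise TopologyError(f"{path}: bead {name!r} has non-positive mass")
    return dict(beads)


def save_topology_map(beads: Mapping[str, Mapping], path: str | Path) -> None:
    payload = {"beads": {str(k): {"group": v["group"],
                                  "species": v["species"],
                                  "mass": float(v["mass"])}
                         for k, v in beads.items()}}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def topology_from_map(names: Sequence[str], resids: Sequence[int],
                      bead_map: Mapping[str, Mapping]) -> BeadTopology:
    """Build a validated BeadTopology for beads read from a coordinate file.

    ``resids`` are the file's residue numbers (any origin, renumbered to
    contiguous 0-based molecule ids). Unknown bead names raise unless the map
    assigns them group "other".
    """
    names = list(names)
    group, species, mass = [], [], []
    for nm in names:
        if nm not in bead_map:
            raise TopologyError(
                f"bead name {nm!r} not in topology map; map it explicitly "
                "(use group 'other' to ignore)")
        entry = bead_map[nm]
        group.append(entry["group"])
        species.append(entry["species"])
        mass.append(float(entry["mass"]))
    # renumber molecules contiguously in order of first appearance
    resids = np.asarray(resids)
    _, mol = np.unique(resids, return_inverse=True)
    # np.unique sorts; preserve order of first appearance instead
    first = {r: i for i, r in enumerate(dict.fromkeys(resids.tolist()))}
    mol = np.array([first[r] for r in resids.tolist()])
    return BeadTopology(names=np.array(names, dtype=object),
                        molecule_id=mol,
                        group=np.array(group, dtype=object),
                        species=np.array(species, dtype=object),
                        mass=np.array(mass))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _check_orthorhombic(cell: np.ndarray, frame: int) -> np.ndarray:
    """3x3 unitcell vectors -> (Lx, Ly, Lz); rejects triclinic cells."""
    off = cell - np.diag(np.diag(cell))
    if np.any(np.abs(off) > 1e-6):
        raise TrajectoryParseError(
            f"frame {frame}: triclinic box not supported (orthorhombic only)")
    box = np.diag(cell).astype(float)
    if np.any(box <= 0):
        raise TrajectoryParseError(f"frame {frame}: non-positive box {box}")
    return box


def read_trajectory(path: str | Path, topology_map: str | Path,
                    top: str | Path | None = None) -> Trajectory:
    """Read a multi-frame GRO (or XTC + reference GRO) into a Trajectory.

    Parameters
    ----------
    path : coordinate file; ``.gro`` (multi-frame concatenation accepted) or
        ``.xtc`` (requires ``top``, a single-frame GRO carrying bead names).
    topology_map : YAML config assigning every bead name a group/species/mass.
    top : reference GRO for binary trajectories.
    """
    import mdtraj.formats as fmts

    path = Path(path)
    bead_map = load_topology_map(topology_map)

    if path.suffix == ".xtc":
        if top is None:
            raise ValueError("XTC input needs a reference GRO via top=")
        names, resids = _read_gro_names(Path(top))
        with fmts.XTCTrajectoryFile(str(path)) as fh:
            xyz, times, step, cells = fh.read()
        times = np.asarray(times, dtype=float)
    else:
        names, resids = _read_gro_names(path)
        try:
            with fmts.GroTrajectoryFile(str(path)) as fh:
                xyz, times, cells = fh.read()
        except Exception as exc:  # mdtraj raises assorted parse errors
            raise TrajectoryParseError(f"{path}: {exc}") from exc
        times = np.asarray(times, dtype=float)

    xyz = np.asarray(xyz, dtype=np.float64)
    if xyz.shape[0] == 0:
        raise TrajectoryParseError(f"{path}: no frames")
    if xyz.shape[1] != len(names):
        raise TrajectoryParseError(
            f"{path}: frame bead count {xyz.shape[1]} != topology count "
            f"{len(names)}")
    boxes = np.stack([_check_orthorhombic(np.asarray(cells[i], dtype=float), i)
                      for i in range(xyz.shape[0])])
    topo = topology_from_map(names, resids, bead_map)
    if np.any(np.diff(times) <= 0):
        # GRO files without parseable t= comments come back with zero times
        times = np.arange(xyz.shape[0], dtype=float)
    return Trajectory(topology=topo, coords=xyz, boxes=boxes, times=times)


def _read_gro_names(path: Path) -> tuple[list[str], list[int]]:
    """Bead names and residue ids of the first frame of a GRO file."""
    with open(path) as fh:
        fh.readline()  # title
        try:
            n = int(fh.readline().split()[0])
        except (ValueError, IndexError) as exc:
            raise TrajectoryParseError(f"{path}: bad atom-count line") from exc
        names, resids = [], []
        for i in range(n):
            line = fh.readline()
            if len(line) < 20:
                raise TrajectoryParseError(
                    f"{path}: frame 0 truncated at atom {i + 1}")
            resids.append(int(line[0:5]))
            names.append(line[10:15].strip())
    return names, resids


def write_trajectory(traj: Trajectory, path: str | Path,
                     title: str = "memlens") -> None:
    """Write all frames as concatenated fixed-column GRO records."""
    topo = traj.topology
    names = topo.names.astype(str)
    species = topo.species.astype(str)
    resid = topo.molecule_id + 1  # 1-based at the file boundary
    with open(path, "w") as fh:
        for i in range(traj.n_frames):
            fh.write(f"{title} t={traj.times[i]:.4f}\n")
            fh.write(f"{topo.n_beads:5d}\n")
            c = traj.coords[i]
            for j in range(topo.n_beads):
                fh.write(f"{resid[j] % 100000:5d}{species[j][:5]:<5s}"
                         f"{names[j][:5]:>5s}{(j + 1) % 100000:5d}"
                         f"{c[j, 0]:8.3f}{c[j, 1]:8.3f}{c[j, 2]:8.3f}\n")
            b = traj.boxes[i]
            fh.write(f"{b[0]:10.5f}{b[1]:10.5f}{b[2]:10.5f}\n")


# ---------------------------------------------------------------------------
# periodic-boundary geometry
# ---------------------------------------------------------------------------

def minimum_image_displacement(a: np.ndarray, b: np.ndarray,
                               box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement vector(s) b - a under an orthorhombic box."""
    box = np.asarray(box, dtype=np.float64)
    if np.any(box <= 0):
        raise ValueError("box components must be positive")
    d = np.asarray(b, dtype=np.float64) - np.asarray(a, dtype=np.float64)
    return d - box * np.round(d / box)


def minimum_image_distance(a: np.ndarray, b: np.ndarray,
                           box: np.ndarray) -> float | np.ndarray:
    """Minimum distance between a and b over all periodic images."""
    d = minimum_image_displacement(a, b, box)
    return np.linalg.norm(d, axis=-1)


def center_of_mass(coords: np.ndarray, masses: np.ndarray,
                   box: np.ndarray | None = None,
                   pbc: bool = False) -> np.ndarray:
    """Mass-weighted mean position; periodic-safe when ``pbc`` is set.

    With ``pbc`` each axis is averaged on the circle (map x to an angle
    theta = 2 pi x / L, average the unit vectors, map back), so molecules
    split across the boundary get the physically correct center of mass.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=np.float64))
    masses = np.asarray(masses, dtype=np.float64)
    if coords.shape[0] == 0:
        raise ValueError("empty selection")
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    if masses.shape[0] != coords.shape[0]:
        raise ValueError("masses length mismatch")
    if not pbc:
        return masses @ coords / masses.sum()
    if box is None:
        raise ValueError("pbc center of mass needs a box")
    box = np.asarray(box, dtype=np.float64)
    theta = 2 * np.pi * coords / box
    xi = (masses @ np.cos(theta)) / masses.sum()
    zeta = (masses @ np.sin(theta)) / masses.sum()
    ang = np.arctan2(zeta, xi)
    return (box * ang / (2 * np.pi)) % box
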