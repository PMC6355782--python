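"""Synthetic coarse-grained slab systems with known statistical structure.

Every analysis stage in this package is validated against trajectories whose
ground truth is analytic or enumerable:

* :func:`generate_slab_membrane` — a two-leaflet slab of labelled lipid beads
  on a jittered lattice with controllable area per lipid and head-plane
  separation (plus optional Gaussian box-area fluctuations and water beads),
  so membrane dimension estimators close the loop on their own inputs.
* :func:`sample_particles_mc` — Metropolis samples of nanoparticles under a
  truncated-and-shifted 12-6 pair potential and an optional layering field
  w(z); in the dilute limit g(r) = exp(-u(r)/kB T), giving the Boltzmann
  inversion a closed-form target.
* :func:`simulate_brownian` — overdamped non-interacting particles with a
  known diffusion constant, the ground truth for the MSD estimators.

A fixed seed gives byte-identical output.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import _mc
from .constants import KB
from .core import BeadTopology, Trajectory, save_topology_map

__all__ = [
    "PairPotential",
    "LayeringField",
    "SamplerConfig",
    "SyntheticSpec",
    "generate_slab_membrane",
    "sample_particles_mc",
    "simulate_brownian",
    "combine",
    "metropolis_transition_matrix",
]

log = logging.getLogger(__name__)

#: bead mass used for all synthetic beads (amu, one Martini bead)
BEAD_MASS = 72.0
#: spacing between successive tail beads along z (nm)
TAIL_SPACING = 0.47
#: in-plane lattice jitter (nm)
LATTICE_JITTER = 0.05


@dataclass(frozen=True)
class PairPotential:
    """Truncated-and-shifted 12-6 potential u(r) (kJ/mol, nm)."""

    epsilon: float = 2.0
    sigma: float = 0.9
    cutoff: float = 1.2
    form: str = "lj126_truncated_shifted"

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.sigma <= 0 or self.cutoff <= 0:
            raise ValueError("sigma and cutoff must be positive")
        if self.form != "lj126_truncated_shifted":
            raise ValueError(f"unsupported pair potential form {self.form!r}")

    def __call__(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        with np.errstate(divide="ignore"):
            sr6 = (self.sigma / r) ** 6
        u = 4 * self.epsilon * (sr6**2 - sr6)
        src6 = (self.sigma / self.cutoff) ** 6
        u_c = 4 * self.epsilon * (src6**2 - src6)
        return np.where(r < self.cutoff, u - u_c, 0.0)


@dataclass(frozen=True)
class LayeringField:
    """External potential w(z) acting on nanoparticles (kJ/mol).

    kind "harmonic": w(z) = 0.5 k z^2, a single well centred on the midplane.
    kind "cosine3":  w(z) = -A cos(6 pi z / h) inside |z| < h/2 — three wells
    at z = 0 and z = +/- h/3, emulating the three-region layering seen in
    unsaturated bilayers — with a soft harmonic wall beyond |z| = h/2.
    """

    kind: str = "cosine3"
    k: float = 2.478                 # harmonic stiffness, kJ/mol/nm^2
    amplitude: float = 2.0           # cosine amplitude A, kJ/mol
    width: float = 4.0               # cosine region h, nm
    wall: float = 50.0               # wall stiffness, kJ/mol/nm^2

    def __post_init__(self) -> None:
        if self.kind not in ("harmonic", "cosine3"):
            raise ValueError(f"unknown layering field kind {self.kind!r}")

    def __call__(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if self.kind == "harmonic":
            return 0.5 * self.k * z**2
        inside = np.abs(z) < self.width / 2
        excess = np.abs(z) - self.width / 2
        return np.where(inside, -self.amplitude * np.cos(6 * np.pi * z / self.width),
                        self.amplitude + self.wall * excess**2)

    def _mc_params(self) -> tuple[int, float, float, float]:
        if self.kind == "harmonic":
            return _mc.FIELD_HARMONIC, self.k, 0.0, 0.0
        return _mc.FIELD_COSINE3, self.amplitude, self.width, self.wall


@dataclass(frozen=True)
class SamplerConfig:
    """How particle positions are generated.

    mode "metropolis": n_steps sweeps, first half burn-in, one frame every
    frame_stride sweeps, trial displacements uniform in a cube of half-width
    step_size. mode "brownian": n_frames steps of length dt (ns) along the
    unit axes in `axes`.
    """

    mode: str = "metropolis"
    n_steps: int = 20_000
    step_size: float = 0.3           # nm
    n_frames: int = 1_000
    frame_stride: int = 10
    dt: float = 0.1                  # ns, brownian mode
    axes: tuple[int, ...] = (0, 1, 2)

    def __post_init__(self) -> None:
        if self.mode not in ("metropolis", "brownian"):
            raise ValueError(f"unknown sampler mode {self.mode!r}")
        if self.n_steps < 1 or self.n_frames < 1 or self.frame_stride < 1:
            raise ValueError("n_steps, n_frames, frame_stride must be >= 1")
        if self.step_size <= 0 or self.dt <= 0:
            raise ValueError("step_size and dt must be positive")


@dataclass(frozen=True)
class SyntheticSpec:
    """Complete description of a synthetic slab system.

    Defaults mirror the study conditions this package targets: 512 lipids at
    0.64 nm^2 per lipid (12.8 x 12.8 nm box), a 4.0 nm head-plane separation,
    298 K, and a 1.2 nm interaction cutoff.
    """

    n_lipids: int = 512
    n_particles: int = 0
    box: tuple[float, float, float] = (12.8, 12.8, 10.0)
    target_apl: float = 0.64         # nm^2
    head_separation: float = 4.0     # nm
    lipid_species: str = "DPPC"
    with_double_bond: bool = False   # label the 2nd tail bead as double_bond
    n_waters: int = 0
    area_sd: float = 0.0             # nm^2, per-frame Gaussian box-area jitter
    n_frames: int = 1
    pair_potential: PairPotential = field(default_factory=PairPotential)
    layering_field: LayeringField | None = None
    temperature: float = 298.0       # K
    seed: int = 0
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    diffusion_constant: float = 0.01  # nm^2/ns, brownian mode

    def __post_init__(self) -> None:
        if self.n_lipids < 0 or self.n_lipids % 2:
            raise ValueError("n_lipids must be even (two leaflets)")
        if any(b <= 0 for b in self.box):
            raise ValueError("box components must be positive")
        if self.head_separation >= self.box[2]:
            raise ValueError("head_separation must be < Lz")
        if self.n_lipids:
            area = self.box[0] * self.box[1]
            want = self.target_apl * self.n_lipids / 2
            if abs(area - want) > 0.01 * area:
                raise ValueError(
                    f"lattice cannot host {self.n_lipids // 2} lipids per "
                    f"leaflet at APL {self.target_apl} in a "
                    f"{self.box[0]} x {self.box[1]} box "
                    f"({want:.2f} vs {area:.2f} nm^2)")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.diffusion_constant < 0:
            raise ValueError("diffusion_constant must be >= 0")

    def replace(self, **kw) -> "SyntheticSpec":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# membrane scaffold
# ---------------------------------------------------------------------------

def _lattice_shape(n_per_leaflet: int, lx: float, ly: float) -> tuple[int, int]:
    nx = int(round(np.sqrt(n_per_leaflet * lx / ly)))
    for cand in (nx, nx - 1, nx + 1, nx - 2, nx + 2):
        if cand > 0 and n_per_leaflet % cand == 0:
            return cand, n_per_leaflet // cand
    raise ValueError(
        f"cannot factor {n_per_leaflet} lipids per leaflet onto a lattice "
        f"matching the {lx} x {ly} box aspect")


def _membrane_topology(spec: SyntheticSpec) -> tuple[BeadTopology, dict]:
    """Topology and topology-map dict for the lipid + water scaffold."""
    names, groups, species, mol = [], [], [], []
    bead_map = {}
    per_lipid = [("HD", "lipid_head"), ("T1", "lipid_tail"),
                 ("T2", "double_bond" if spec.with_double_bond else "lipid_tail"),
                 ("T3", "lipid_tail")]
    for nm, grp in per_lipid:
        bead_map[nm] = {"group": grp, "species": spec.lipid_species,
                        "mass": BEAD_MASS}
    for i in range(spec.n_lipids):
        for nm, grp in per_lipid:
            names.append(nm)
            groups.append(grp)
            species.append(spec.lipid_species)
            mol.append(i)
    for j in range(spec.n_waters):
        names.append("W")
        groups.append("water")
        species.append("W")
        mol.append(spec.n_lipids + j)
    if spec.n_waters:
        bead_map["W"] = {"group": "water", "species": "W", "mass": BEAD_MASS}
    topo = BeadTopology(names=np.array(names, dtype=object),
                        molecule_id=np.array(mol),
                        group=np.array(groups, dtype=object),
                        species=np.array(species, dtype=object),
                        mass=np.full(len(names), BEAD_MASS))
    return topo, bead_map


def generate_slab_membrane(spec: SyntheticSpec) -> Trajectory:
    """Build a static two-leaflet slab trajectory (midplane at z = 0).

    Each lipid is a head bead at +/- head_separation/2 with three tail beads
    at fixed 0.47 nm spacing pointing inward, placed on a jittered square
    lattice (Gaussian jitter sigma 0.05 nm in-plane). With ``area_sd`` > 0
    the box area fluctuates per frame as an independent Gaussian, coordinates
    rescaled affinely with the box.
    """
    if spec.n_lipids == 0:
        raise ValueError("membrane needs lipids; set n_lipids > 0")
    rng = np.random.default_rng(spec.seed)
    lx, ly, lz = spec.box
    half = spec.n_lipids // 2
    nx, ny = _lattice_shape(half, lx, ly)
    ax, ay = lx / nx, ly / ny
    h2 = spec.head_separation / 2

    coords = np.empty((spec.n_lipids * 4 + spec.n_waters, 3))
    b = 0
    for leaflet, sign in ((0, 1.0), (1, -1.0)):
        for ix in range(nx):
            for iy in range(ny):
                x = (ix + 0.5) * ax + rng.normal(0, LATTICE_JITTER)
                y = (iy + 0.5) * ay + rng.normal(0, LATTICE_JITTER)
                x = (x + lx / 2) % lx - lx / 2
                y = (y + ly / 2) % ly - ly / 2
                for t in range(4):  # head + 3 tail beads, inward
                    z = sign * (h2 - t * TAIL_SPACING)
                    coords[b] = (x, y, z)
                    b += 1
    if spec.n_waters:
        # water fills the region beyond the head planes
        zw = rng.uniform(h2 + 0.3, lz / 2, size=spec.n_waters)
        zw *= rng.choice([-1.0, 1.0], size=spec.n_waters)
        coords[b:, 0] = rng.uniform(-lx / 2, lx / 2, size=spec.n_waters)
        coords[b:, 1] = rng.uniform(-ly / 2, ly / 2, size=spec.n_waters)
        coords[b:, 2] = zw

    topo, bead_map = _membrane_topology(spec)
    nf = spec.n_frames
    all_coords = np.repeat(coords[None], nf, axis=0)
    boxes = np.repeat(np.array([[lx, ly, lz]]), nf, axis=0)
    if spec.area_sd > 0:
        a0 = lx * ly
        areas = rng.normal(a0, spec.area_sd, size=nf)
        areas = np.clip(areas, 0.5 * a0, 1.5 * a0)
        s = np.sqrt(areas / a0)
        all_coords[:, :, 0] *= s[:, None]
        all_coords[:, :, 1] *= s[:, None]
        boxes[:, 0] = lx * s
        boxes[:, 1] = ly * s
    times = np.arange(nf, dtype=float)
    traj = Trajectory(topo, all_coords, boxes, times, wrapped=True,
                      metadata={"spec": spec, "bead_map": bead_map})
    return traj


# ---------------------------------------------------------------------------
# nanoparticle samplers
# ---------------------------------------------------------------------------

def _particle_topology(n: int) -> tuple[BeadTopology, dict]:
    bead_map = {"CF": {"group": "fullerene", "species": "NP",
                       "mass": 16 * BEAD_MASS}}
    topo = BeadTopology(names=np.array(["CF"] * n, dtype=object),
                        molecule_id=np.arange(n),
                        group=np.array(["fullerene"] * n, dtype=object),
                        species=np.array(["NP"] * n, dtype=object),
                        mass=np.full(n, 16 * BEAD_MASS))
    return topo, bead_map


def _initial_positions(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Random non-overlapping starting positions in the centred box."""
    lx, ly, lz = spec.box
    pot = spec.pair_potential
    min_r = 0.8 * pot.sigma if pot.epsilon > 0 else 0.0
    coords = np.empty((spec.n_particles, 3))
    placed = 0
    for _ in range(200 * max(1, spec.n_particles)):
        if placed == spec.n_particles:
            break
        p = rng.uniform(-0.5, 0.5, 3) * np.array([lx, ly, lz])
        if spec.layering_field is not None and spec.layering_field.kind == "cosine3":
            p[2] = rng.uniform(-0.5, 0.5) * spec.layering_field.width
        ok = True
        for j in range(placed):
            d = p - coords[j]
            d -= np.array(spec.box) * np.round(d / np.array(spec.box))
            if np.linalg.norm(d) < min_r:
                ok = False
                break
        if ok:
            coords[placed] = p
            placed += 1
    if placed < spec.n_particles:
        raise ValueError("could not place particles without overlap; "
                         "box too crowded")
    return coords


def sample_particles_mc(spec: SyntheticSpec) -> Trajectory:
    """Metropolis-sample nanoparticle positions at spec.temperature.

    One sweep attempts one move per particle; the first half of
    ``sampler.n_steps`` sweeps is discarded as burn-in and one frame is
    recorded every ``sampler.frame_stride`` sweeps thereafter. The acceptance
    rate is logged and stored in ``Trajectory.metadata``; rates outside
    [0.1, 0.9] trigger a warning.
    """
    if spec.sampler.mode != "metropolis":
        raise ValueError("sampler.mode must be 'metropolis'")
    if spec.n_particles < 1:
        raise ValueError("need n_particles >= 1")
    rng = np.random.default_rng(spec.seed)
    coords0 = _initial_positions(spec, rng)
    pot = spec.pair_potential
    fkind, p1, p2, p3 = (spec.layering_field._mc_params()
                         if spec.layering_field is not None
                         else (_mc.FIELD_NONE, 0.0, 0.0, 0.0))
    # sanity: starting energy must be finite
    e0 = float(np.sum(pot(_pair_distances(coords0, np.array(spec.box)))))
    if spec.layering_field is not None:
        e0 += float(np.sum(spec.layering_field(coords0[:, 2])))
    if not np.isfinite(e0):
        raise ValueError("non-finite initial energy")

    beta = 1.0 / (KB * spec.temperature)
    n_sweeps = spec.sampler.n_steps
    burn_in = n_sweeps // 2
    mc_seed = int(rng.integers(0, 2**31 - 1))
    frames, acc, att = _mc.run_metropolis(
        coords0.copy(), np.array(spec.box, dtype=float),
        pot.epsilon, pot.sigma, pot.cutoff, fkind, p1, p2, p3,
        beta, n_sweeps, spec.sampler.step_size, burn_in,
        spec.sampler.frame_stride, mc_seed)
    if not np.isfinite(frames).all():
        raise ValueError("non-finite coordinates produced by sampler")
    rate = acc / att if att else 0.0
    log.info("metropolis acceptance rate %.3f (%d/%d moves)", rate, acc, att)
    if not 0.1 <= rate <= 0.9:
        warnings.warn(f"Metropolis acceptance rate {rate:.3f} outside "
                      "[0.1, 0.9]; adjust step_size", stacklevel=2)
    topo, bead_map = _particle_topology(spec.n_particles)
    nf = frames.shape[0]
    boxes = np.repeat(np.array([spec.box], dtype=float), nf, axis=0)
    traj = Trajectory(topo, frames, boxes, np.arange(nf, dtype=float),
                      wrapped=True,
                      metadata={"spec": spec, "bead_map": bead_map,
                                "acceptance_rate": rate})
    return traj


def _pair_distances(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    n = coords.shape[0]
    if n < 2:
        return np.empty(0)
    d = coords[:, None, :] - coords[None, :, :]
    d -= box * np.round(d / box)
    r = np.sqrt((d**2).sum(-1))
    iu = np.triu_indices(n, 1)
    return r[iu]


def simulate_brownian(spec: SyntheticSpec,
                      return_unwrapped: bool = False):
    """Overdamped Brownian trajectories with known diffusion constant.

    Per frame and axis in ``sampler.axes``: x <- x + sqrt(2 D dt) eta with
    eta ~ N(0, 1); positions are wrapped into the centred box, and the exact
    unwrapped path is returned alongside when ``return_unwrapped`` is set.
    Raises if any single step exceeds a quarter box (which would break the
    minimum-image unwrapping contract downstream).
    """
    if spec.sampler.mode != "brownian":
        raise ValueError("sampler.mode must be 'brownian'")
    if spec.n_particles < 1:
        raise ValueError("need n_particles >= 1")
    rng = np.random.default_rng(spec.seed)
    box = np.array(spec.box, dtype=float)
    nf = spec.sampler.n_frames
    dt = spec.sampler.dt
    n = spec.n_particles
    start = rng.uniform(-0.5, 0.5, size=(n, 3)) * box
    sigma_step = np.sqrt(2 * spec.diffusion_constant * dt)
    steps = np.zeros((nf - 1, n, 3)) if nf > 1 else np.zeros((0, n, 3))
    if sigma_step > 0 and nf > 1:
        for ax in spec.sampler.axes:
            steps[:, :, ax] = rng.normal(0, sigma_step, size=(nf - 1, n))
    if steps.size and np.abs(steps).max() > box.min() / 4:
        raise ValueError("per-step displacement exceeds box/4; reduce dt or D")
    unwrapped = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
    wrapped = (unwrapped + box / 2) % box - box / 2
    topo, bead_map = _particle_topology(n)
    boxes = np.repeat(box[None], nf, axis=0)
    times = np.arange(nf, dtype=float) * dt
    meta = {"spec": spec, "bead_map": bead_map}
    traj = Trajectory(topo, wrapped, boxes, times, wrapped=True, metadata=meta)
    if return_unwrapped:
        true = Trajectory(topo, unwrapped, boxes.copy(), times.copy(),
                          wrapped=False, metadata=dict(meta))
        return traj, true
    return traj


# ---------------------------------------------------------------------------
# composition helpers
# ---------------------------------------------------------------------------

def combine(membrane: Trajectory, particles: Trajectory) -> Trajectory:
    """Merge a (static or per-frame) membrane scaffold with particle frames.

    The membrane contributes frame 0 replicated if it has fewer frames than
    the particle trajectory; boxes must agree in x/y.
    """
    nf = particles.n_frames
    mem_coords = (membrane.coords if membrane.n_frames == nf
                  else np.repeat(membrane.coords[:1], nf, axis=0))
    topo_m, topo_p = membrane.topology, particles.topology
    shift = topo_m.n_molecules
    topo = BeadTopology(
        names=np.concatenate([topo_m.names, topo_p.names]),
        molecule_id=np.concatenate([topo_m.molecule_id,
                                    topo_p.molecule_id + shift]),
        group=np.concatenate([topo_m.group, topo_p.group]),
        species=np.concatenate([topo_m.species, topo_p.species]),
        mass=np.concatenate([topo_m.mass, topo_p.mass]))
    coords = np.concatenate([mem_coords, particles.coords], axis=1)
    meta = dict(particles.metadata)
    bead_map = dict(membrane.metadata.get("bead_map", {}))
    bead_map.update(particles.metadata.get("bead_map", {}))
    meta["bead_map"] = bead_map
    return Trajectory(topo, coords, particles.boxes.copy(),
                      particles.times.copy(), wrapped=True, metadata=meta)


def write_system(traj: Trajectory, gro_path, map_path) -> None:
    """Write trajectory plus its matching topology map config."""
    from .core import write_trajectory
    write_trajectory(traj, gro_path)
    bead_map = traj.metadata.get("bead_map")
    if bead_map is None:
        raise ValueError("trajectory carries no bead_map metadata")
    save_topology_map(bead_map, map_path)


# ---------------------------------------------------------------------------
# detailed-balance check helper
# ---------------------------------------------------------------------------

def metropolis_transition_matrix(energies: Sequence[float],
                                 temperature: float) -> np.ndarray:
    """Transition matrix of a Metropolis chain on a discrete state space.

    Uniform proposal over the other states, acceptance min(1, e^(-beta dE)).
    Used to verify detailed balance against the Boltzmann distribution on
    small toy systems.
    """
    e = np.asarray(energies, dtype=float)
    n = len(e)
    if n < 2:
        raise ValueError("need >= 2 states")
    beta = 1.0 / (KB * temperature)
    p = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                p[i, j] = min(1.0, np.exp(-beta * (e[j] - e[i]))) / (n - 1)
        p[i, i] = 1.0 - p[i].sum()
    return p
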