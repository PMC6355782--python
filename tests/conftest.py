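import numpy as np
import pytest

from memlens.core import BeadTopology, Trajectory


def make_particle_topology(n, group="fullerene", species="NP", mass=100.0):
    return BeadTopology(
        names=np.array(["CF"] * n, dtype=object),
        molecule_id=np.arange(n),
        group=np.array([group] * n, dtype=object),
        species=np.array([species] * n, dtype=object),
        mass=np.full(n, mass))


def make_particle_trajectory(coords, box, times=None, wrapped=True):
    """Trajectory of single-bead 'fullerene' particles from raw coords."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    nf, n, _ = coords.shape
    boxes = np.repeat(np.asarray(box, dtype=float)[None], nf, axis=0)
    if times is None:
        times = np.arange(nf, dtype=float)
    return Trajectory(make_particle_topology(n), coords, boxes,
                      np.asarray(times, dtype=float), wrapped=wrapped)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_gro(tmp_path):
    """Hand-written 1-frame GRO fixture (3 beads) plus its topology map."""
    gro = tmp_path / "tiny.gro"
    gro.write_text(
        "tiny t=0.0\n"
        "    3\n"
        "    1DPPC   HD    1   1.000   2.000   3.000\n"
        "    1DPPC   T1    2   1.100   2.100   3.100\n"
        "    2NP     CF    3   5.000   5.000   5.000\n"
        "  10.00000  10.00000  10.00000\n")
    topmap = tmp_path / "tiny.topmap.yaml"
    topmap.write_text(
        "beads:\n"
        "  HD: {group: lipid_head, species: DPPC, mass: 72.0}\n"
        "  T1: {group: lipid_tail, species: DPPC, mass: 72.0}\n"
        "  CF: {group: fullerene, species: NP, mass: 720.0}\n")
    return gro, topmap
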