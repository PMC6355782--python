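"""Numba kernels for the Metropolis nanoparticle sampler.

Single-particle displacement moves under a truncated-and-shifted 12-6 pair
potential plus an optional external layering field w(z), minimum-image
convention in an orthorhombic box. Coordinates live in the centred box
[-L/2, L/2) per axis.
"""

import numpy as np
from numba import njit

FIELD_NONE = 0
FIELD_HARMONIC = 1      # w(z) = 0.5 * k * z^2          (p1 = k)
FIELD_COSINE3 = 2       # w(z) = -A cos(6 pi z / h) for |z| < h/2, wall beyond
                        # (p1 = A, p2 = h, p3 = wall stiffness)


@njit(cache=True)
def lj_ts(r2, eps, sigma, cutoff):
    """Truncated-and-shifted 12-6 potential evaluated at squared distance."""
    if r2 >= cutoff * cutoff:
        return 0.0
    sr2 = sigma * sigma / r2
    sr6 = sr2 * sr2 * sr2
    src2 = sigma * sigma / (cutoff * cutoff)
    src6 = src2 * src2 * src2
    return 4.0 * eps * (sr6 * sr6 - sr6) - 4.0 * eps * (src6 * src6 - src6)


@njit(cache=True)
def field_energy(z, kind, p1, p2, p3):
    if kind == FIELD_HARMONIC:
        return 0.5 * p1 * z * z
    if kind == FIELD_COSINE3:
        h = p2
        if np.abs(z) < 0.5 * h:
            return -p1 * np.cos(6.0 * np.pi * z / h)
        excess = np.abs(z) - 0.5 * h
        return p1 + p3 * excess * excess
    return 0.0


@njit(cache=True)
def particle_energy(i, pos, coords, box, eps, sigma, cutoff,
                    fkind, p1, p2, p3):
    """Energy of particle i at trial position `pos` with all others fixed."""
    e = field_energy(pos[2], fkind, p1, p2, p3)
    n = coords.shape[0]
    for j in range(n):
        if j == i:
            continue
        r2 = 0.0
        for k in range(3):
            d = pos[k] - coords[j, k]
            d -= box[k] * np.round(d / box[k])
            r2 += d * d
        e += lj_ts(r2, eps, sigma, cutoff)
    return e


@njit(cache=True)
def run_metropolis(coords, box, eps, sigma, cutoff, fkind, p1, p2, p3,
                   beta, n_sweeps, step, burn_in, stride, seed):
    """Run Metropolis sampling; returns (frames, n_accepted, n_attempted).

    One sweep = one attempted move per particle. Frames are recorded every
    `stride` sweeps once `burn_in` sweeps have elapsed.
    """
    np.random.seed(seed)
    n = coords.shape[0]
    n_rec = 0
    for s in range(n_sweeps):
        if s >= burn_in and (s - burn_in) % stride == 0:
            n_rec += 1
    frames = np.empty((n_rec, n, 3))
    trial = np.empty(3)
    acc = 0
    att = 0
    rec = 0
    for s in range(n_sweeps):
        for i in range(n):
            for k in range(3):
                trial[k] = coords[i, k] + step * (2.0 * np.random.random() - 1.0)
                # wrap into centred box
                trial[k] -= box[k] * np.round(trial[k] / box[k])
            e_old = particle_energy(i, coords[i], coords, box, eps, sigma,
                                    cutoff, fkind, p1, p2, p3)
            e_new = particle_energy(i, trial, coords, box, eps, sigma,
                                    cutoff, fkind, p1, p2, p3)
            att += 1
            de = e_new - e_old
            if de <= 0.0 or np.random.random() < np.exp(-beta * de):
                for k in range(3):
                    coords[i, k] = trial[k]
                acc += 1
        if s >= burn_in and (s - burn_in) % stride == 0:
            for i in range(n):
                for k in range(3):
                    frames[rec, i, k] = coords[i, k]
            rec += 1
    return frames, acc, att
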