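# Methods

`memlens` analyses coarse-grained membrane trajectories in which spherical
carbon nanoparticles (fullerenes, modelled as bead cages whose centre of mass
is the analysis particle) are embedded in a lipid bilayer. This note records
the models, estimators, numerical choices and their limits.

## Units and conventions

Lengths nm, energies kJ/mol, times ns, masses amu; kB = 0.0083145
kJ/(mol K), so kB·T = 2.478 kJ/mol at 298 K. Boxes are orthorhombic only;
triclinic input is rejected rather than silently mishandled. Beads are
0-indexed internally, 1-based only in GRO files. Coordinates follow the GRO
convention (nm); the synthetic generator builds systems in a centred box
(midplane at z = 0), which is immaterial to every analysis because all
distances use the minimum-image convention.

Group labels (`lipid_head`, `lipid_glycerol`, `lipid_tail`, `double_bond`,
`fullerene`, `water`, `other`) are assigned by an explicit topology-map
config, never inferred from bead names: coarse-grained bead names (NC3, PO4,
D3B, ...) vary by lipid and force-field version, so an auditable mapping file
is the only safe interface.

## Periodic geometry

Minimum-image displacements use the component-wise nearest-image map of an
orthorhombic box (equivalent to the 27-image minimum, which the tests check
by brute force). Centres of mass of molecules that may straddle the boundary
are computed by the circular-mean construction: each coordinate is mapped to
an angle 2πx/L, the mass-weighted mean unit vector is taken, and its angle
mapped back. This is exact for compact molecules (extent ≪ L) and avoids the
classic artefact where a wrapped molecule's naive COM lands in the box
centre.

## Cluster statistics

Two nanoparticles belong to the same cluster when their COM distance is
strictly below the cutoff (default 1.30 nm — at contact two cages sit near
1.0 nm, so 1.30 separates the first and second coordination shells).
Clusters are connected components of the contact graph. Neighbour search
uses a periodic k-d tree with an exact re-measurement of each candidate pair
(so the strict `<` contract holds at the boundary); results are identical to
the all-pairs union-find oracle on every tested configuration. The reported
statistics — per-frame largest cluster size, cluster count, fraction of
particles in the largest cluster — are averaged over a trailing analysis
window (default: last half of the trajectory) to discard the approach to
equilibrium.

## Pair structure and free energies

The centre-of-mass radial distribution function accumulates 3D minimum-image
pair distances into bins of 0.02 nm by default, up to r_max = min(half box,
3.5 nm). Whether distances in a thin film should be 3D or lateral is a
genuine modelling choice; 3D is used and recorded in every output header.
Three normalizations are exposed and always declared:

* `raw_histogram` — counts, no convention;
* `shell_normalized` — counts divided by the ideal-gas shell expectation
  n_frames · n_pairs · 4πr²Δr / V (appropriate for bulk-like systems, and
  exact for the dilute two-particle benchmark);
* `plateau_normalized` (default) — counts divided by their mean over a
  plateau window (default 2.5–3.2 nm). In slab geometry the 4πr² shell is
  partly empty, so shell normalization never plateaus at 1; pinning the
  large-r plateau fixes the additive free-energy constant explicitly
  instead.

Boltzmann inversion gives ΔG(r) = −kB·T·ln g(r). Empty bins are masked
(NaN + a `defined` flag), never clamped: clamping would fabricate free
energies. Raw-histogram input is rejected because its additive constant is
undefined. Differences such as ΔΔG between minima are independent of the
normalization convention.

Minima are located as the lowest defined bin inside two disjoint search
windows (defaults 0.85–1.25 nm for the contact pair and 1.30–1.75 nm for the
lipid-bead-separated pair — centred on where such systems put them, but
configurable so the result is measured, not assumed), refined by 3-point
quadratic interpolation. The same refinement serves peak positions. Sub-bin
precision without smoothing is the goal; on noisy profiles the position
uncertainty is set by the bin noise relative to the well curvature, which is
why the dilute benchmark uses 0.03 nm bins and long sampling (below).

A split second coordination shell — the short-range-order signature — is
declared when the window 1.30–2.20 nm holds at least two local maxima with
prominence ≥ 2% of the window maximum (prominence implies an intervening
minimum). For two equal Gaussian sub-peaks the analytic merge point is a
separation of exactly 2σ, which the detector reproduces to one bin with the
prominence threshold relaxed.

The pair-axis density takes every COM pair at a chosen separation
(± 0.05 nm), erects a local axis through the pair midpoint, and histograms
beads within a 0.5 nm cylinder radius by axial coordinate, averaged per
qualifying pair. A lipid-bead peak at axial coordinate zero for 1.5 nm pairs
is the structural signature of the solvent-separated minimum.

## Entropy/enthalpy decomposition

From free-energy profiles at T−ΔT, T, T+ΔT (defaults 283/298/313 K, ΔT =
15 K) on a shared r-grid:

    −TΔS(r) = T·dG/dT ≈ (T / 2ΔT) · [G(T+ΔT) − G(T−ΔT)]
    ΔH(r)   = ΔG(r) + TΔS(r)

The central difference is exact for G affine in T (asserted to machine
precision) and the closure (−TΔS) + ΔH = ΔG holds bin-wise by construction.
Masks propagate: a bin undefined at any temperature is undefined in the
decomposition. All three profiles must use the same normalization mode and
plateau window — mixing conventions injects a spurious temperature
dependence into the finite difference. A degenerate but instructive
identity: if the *same* sampled g(r) is labelled with all three
temperatures, G(T) = −kB·T·ln g is linear in T and the decomposition returns
−TΔS = ΔG, ΔH = 0 — the profile is purely entropic. The test suite asserts
this exactly.

## Membrane observables

* APL = Lx·Ly / (n_lipids/2) per frame; mean ± SD over frames.
* VPL = (V_box − N_water·v_w − N_np·v_np) / n_lipids with a calibrated water
  bead volume v_w (config item; there is no unique convention for
  partitioning box volume, so the constant is explicit) and v_np defaulting
  to 0 (lipid + particle composite volume).
* Density profiles: per-frame z-histogram of group mass relative to the
  lipid COM (minimum-image), divided by the bin volume, frame-averaged;
  default bin 0.1 nm. Group mass is conserved to <1% for any binning.
* Thickness: head-bead density peak-to-peak distance with quadratic peak
  refinement. This is one of several legitimate thickness definitions
  (peak-to-peak, Luzzati, ...); peak-to-peak is robust when nanoparticles
  crowd the membrane core.
* Area compressibility: K_A = kB·T·⟨A⟩ / Var(A) from total box-area
  fluctuations; uncertainty by block averaging (5 blocks), because area
  fluctuations are strongly time-correlated and naive errors would be
  optimistic. 1 kJ/(mol·nm²) = 1.6606 mN/m.

## Diffusion

Trajectories are unwrapped by accumulating minimum-image frame-to-frame
displacements. A true jump of ≥ L/2 between frames is aliased by the
minimum-image map and cannot be detected after the fact; the unwrapping
contract therefore requires per-frame displacements < L/2 (the Brownian
generator enforces a stricter L/4 step guard at generation time), and the
detectable boundary case raises.

MSD uses all time origins at stride 1 per particle via the FFT
autocorrelation identity, restricted to lags ≤ half the trajectory, with a
standard error across particles. D = slope/(2d) from a least-squares fit
over a fractional lag window (default 0.1–0.5 of the maximum lag). The
default window is a compromise for membrane data where the shortest lags can
carry sampling artefacts; for free Brownian motion the estimator noise
*grows* with lag (the long-lag MSD of a random walk is dominated by a few
effective observations), so the recovery benchmarks fit the short-lag window
0–0.02 of max lag, where recovery is within ~2%. With the default long-lag
window the irreducible scatter at 64 particles × 10⁴ frames is 5–15% — a
property of the estimator, not a bug. A fit with r² < 0.9 emits a
confinement warning: z-motion in a membrane saturates and its fitted "D" is
a regime diagnostic, not a free diffusion coefficient.

## Synthetic generator

The generator produces systems whose ground truth is known in closed form;
it makes no claim of force-field fidelity (no lipid dynamics, no pressure
coupling, no self-assembly).

* **Slab membrane** — two leaflets on a jittered square lattice (in-plane
  Gaussian jitter σ = 0.05 nm), head bead at ±head_separation/2 and three
  tail beads inward at 0.47 nm spacing (the second tail bead optionally
  labelled `double_bond` for unsaturated species). Defaults mirror the
  target study conditions: 512 lipids, APL 0.64 nm² (12.8 × 12.8 nm box),
  head separation 4.0 nm, 298 K. Optional per-frame Gaussian box-area
  fluctuations (affine xy rescale) feed the compressibility estimator;
  optional water beads fill the region beyond the head planes.
* **Metropolis sampler** — nanoparticles under a truncated-and-shifted 12-6
  pair potential (default ε = 2 kJ/mol, σ = 0.9 nm, cutoff 1.2 nm, matching
  the interaction cutoff such coarse-grained simulations use; note the
  truncation at 1.2 nm with σ = 0.9 removes a large part of the well — at
  ε = 6 the effective depth is ≈ 2.5 kJ/mol) plus an optional layering field
  w(z). Single-particle moves, uniform in a cube of half-width 0.3 nm; one
  sweep = one attempted move per particle; the first half of all sweeps is
  burn-in; frames are recorded at a fixed sweep stride; the acceptance rate
  is logged and warned about outside [0.1, 0.9]. Detailed balance is
  verified on a discrete toy state space via the explicit transition matrix.
  In the dilute two-particle limit g(r) = exp(−u/kB·T) exactly, giving the
  whole RDF→PMF chain a closed-form target.
* **Layering field** — `harmonic` (½kz², Boltzmann z-variance kB·T/k, used
  as a closed-form density-profile target) or `cosine3`: w(z) =
  −A·cos(6πz/h) for |z| < h/2 with a soft harmonic wall outside. The
  three-well form (wells at z = 0, ±h/3, default A = 2 kJ/mol) emulates the
  three-region layering that double-bond-bearing bilayers impose on embedded
  nanoparticles; a cosine with wells only at ±h/3 would produce two maxima,
  not three, hence this parameterization.
* **Brownian dynamics** — overdamped non-interacting updates x ← x +
  √(2DΔt)·η per enabled axis, with the exact unwrapped path retained, so
  diffusion estimators can be checked against both the input D and the true
  path. Steps larger than a quarter box raise.

Fixed seed ⇒ byte-identical output files. What the generator does *not*
emulate: lipid conformational dynamics, undulations, leaflet asymmetry,
hydrodynamics, and any coupling between particles and lipids beyond a static
external field. Passing the closed-loop tests therefore validates the
*estimators*, not any claim about real membranes.

## Problem sizes in tests and the acceptance script

Chosen so each ground truth is measured with comfortable statistical margin:
the dilute PMF benchmark runs 6.4 × 10⁷ sweeps of 2 particles with 0.03 nm
bins (bin noise ≪ the ~0.1 kJ/mol curvature scale of the shallow
truncated-LJ minimum, pinning its position to ±0.02 nm); the ideal-gas null
uses 32 particles × 3000 frames with empirical block standard errors; the
diffusion recovery uses 64 particles × 10⁴ frames; the
repulsive-vs-attractive contrast compares ε = 0 and ε = 6 kJ/mol at matched
density (24 particles, 6.5 nm box) across 5 paired seeds, where the
attractive system shows a larger mean largest cluster and a ΔΔG lower by
~1.5 kJ/mol — the small-system analogue of the dispersion→aggregation
transition.

## Known limitations

* Orthorhombic boxes only; no velocities; no trajectory editing beyond
  unwrapping.
* The plateau normalization presumes the chosen window is structureless; at
  very high particle densities or tiny boxes the plateau may not exist, and
  the error message says so.
* `largest_cluster_series` and the RDF assume the analysis window is
  equilibrated; the window fraction is a parameter, not a convergence test.
* The pair-axis density loops over qualifying pairs in Python; it is meant
  for the sparse pair counts that the separation tolerance implies, not for
  all-pairs accumulation.
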