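# memlens

Trajectory analysis of nanoparticle aggregation in coarse-grained lipid
bilayers — for simulators who want the full observable chain behind the
question *"do fullerenes disperse or aggregate inside a membrane, and why?"*
as tested, reusable code rather than one-off scripts.

Given a multi-frame GRO (or XTC) trajectory and an explicit bead→group
topology map, `memlens` computes:

* **Membrane dimensions** — area per lipid APL = LxLy/(N/2), volume per
  lipid, head-peak-to-peak bilayer thickness, mass density profiles ρ(z),
  and the isothermal area compressibility K_A = k_BT⟨A⟩/Var(A);
* **Cluster statistics** — connected components of the nanoparticle
  centre-of-mass contact graph (minimum image, distance < 1.30 nm by
  default), largest-cluster size and fraction over an analysis window;
* **Pair structure** — centre-of-mass RDF g(r) with declared normalization
  conventions, Boltzmann inversion ΔG(r) = −k_BT ln g(r), contact
  (~1.0 nm) and solvent-separated (~1.5 nm) minima with sub-bin refinement
  and ΔΔG between them, split-second-peak detection, and the in-plane bead
  density along the axis joining particle pairs;
* **Thermodynamics** — entropy/enthalpy decomposition from simulations at
  three temperatures: −TΔS = T·dG/dT ≈ (T/2ΔT)[G(T+ΔT) − G(T−ΔT)],
  ΔH = ΔG + TΔS;
* **Dynamics** — PBC unwrapping, all-origin MSD (FFT), lateral and normal
  diffusion coefficients D = slope/(2d) with confinement diagnostics.

Because such analyses are usually validated against nothing, the package
ships a seeded synthetic generator (`memlens.synthetic`) producing slab
membranes, Metropolis-sampled nanoparticles under a known pair potential
(dilute limit: g(r) = e^(−u/k_BT) exactly), and Brownian trajectories with a
known diffusion constant — every estimator closes the loop on an analytic
ground truth, and the test suite asserts it.

## Worked example

A single YAML config drives the whole sweep. Generate a 128-lipid slab
(APL 0.64 nm², head-plane separation 4.0 nm) hosting 16 attractive
nanoparticles (truncated-shifted 12-6, ε = 6 kJ/mol, σ = 0.9 nm) and analyse
it:

```yaml
# config.yaml
seed: 7
outdir: out
systems:
  - name: demo
    generate:
      n_lipids: 128
      n_particles: 16
      box: [6.4, 6.4, 8.0]
      target_apl: 0.64
      head_separation: 4.0
      n_waters: 200
      pair_potential: {epsilon: 6.0, sigma: 0.9}
      sampler: {mode: metropolis, n_steps: 100000, frame_stride: 10, step_size: 0.35}
analyses: [apl, thickness, cluster, rdf, pmf, minima, split]
params: {rdf_bin_width: 0.05, r_max: 2.8, rdf_mode: shell_normalized}
```

```text
$ memlens run config.yaml
system  config_hash   seed  apl_nm2  thickness_nm  mean_largest_cluster  fraction_in_largest  r_min1_nm  dG_min1_kJ_mol  r_min2_nm  dG_min2_kJ_mol  ddG_kJ_mol  second_peak_split
  demo  fa93822ade34     7     0.64           4.0                2.7424               0.1714   1.019191       -2.324456   1.679998       -0.133781   -2.190675               True
```

Reading the row: the estimators recover the generator's geometry exactly
(APL 0.64 nm², thickness 4.0 nm — the closed loop). The attractive
particles aggregate: on average the largest cluster holds 2.7 of 16
particles (17%), the free-energy profile has its contact minimum at
1.02 nm ≈ 2^(1/6)·σ with ΔG = −2.3 kJ/mol — roughly k_BT (2.478 kJ/mol at
298 K), i.e. marginally bound — a shallow second minimum near 1.7 nm, and
ΔΔG = −2.2 kJ/mol says the contact pair is favoured over the separated
pair. The split second peak flags emerging short-range order. Per-stage
TSVs (`out/demo.rdf.tsv`, `out/demo.pmf.tsv`, ...) carry every convention
(normalization mode, windows, bin widths) in their headers, and rerunning
with the same seed reproduces the summary byte for byte.

The same analyses are exposed as single subcommands
(`memlens apl|vpl|thickness|density|ka|cluster|rdf|pmf|minima|split|pairaxis|thermo|msd|diffusion`)
on any trajectory + topology-map pair, and as plain library functions
(`memlens.com_rdf`, `memlens.free_energy_profile`, ...).

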