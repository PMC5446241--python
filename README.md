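# flexprobe

Probes of receptor-interface flexibility in molecular-dynamics
trajectories, built around the question of how a flexible receptor such as
the immune checkpoint PD-1 recognises multiple ligands: does the unbound
(apo) ensemble already visit bound-like conformations (conformational
selection), or do ligand contacts drive the interface into shape after
association (induced fit)?

The package implements four trajectory analyses and a ground-truth
synthetic-trajectory generator:

- **Fractional pocket occlusion** — given a set of static reference atom
  positions (e.g. the side-chain atoms of a ligand anchor residue taken
  from a bound cocrystal), report the fraction of frames in which each
  reference atom is overlapped by any simulated atom.  Overlap means the
  distance falls strictly inside the *clash radius*, the sum of the two
  van der Waals radii (Bondi set by default).
- **Open/closed state classification** — two binary order parameters for
  interface side chains: the smaller side-chain heavy-atom RMSD to an
  open/closed reference conformation (Asn66-style), or the nearer χ1
  rotamer angle on the circle (Ile126-style).  Combining both labels maps
  every frame to an interface macrostate (non-bound-like, PD-L1-like
  bound, PD-L2-like bound).
- **Boltzmann free-energy differences** — from the state populations,
  ⟨n_BL⟩/⟨n_NBL⟩ = e^(−ΔG_BL/k_BT), so ΔG_BL = −ln(n_BL/n_NBL) in k_BT
  (T = 300 K), with replicate mean ± SD and the ligand-specific sign
  conventions relating ΔG_BL to ΔG_open.
- **Hydrogen-bond chronology** — per-frame geometric bond detection
  (donor–acceptor ≤ 3.5 Å, donor–H–acceptor ≥ 135°), stable-formation
  times (first present frame of the first 1-ns window with ≥80%
  occupancy), and per-bond lags Δt after a reference event such as the
  key receptor–ligand anchor hydrogen bond.

Trajectories are multi-model PDB files (one `MODEL` per frame); all
coordinates are Å, all times ns.  The synthetic generator produces
two-state Markov side-chain dynamics with prescribed equilibrium
populations, scheduled occlusion fixtures, and scheduled bond-formation
events, each with a manifest recording the hidden ground truth — so the
whole pipeline is testable without an MD engine.

## Worked example

Estimate the free energy of opening a side chain whose true equilibrium
open probability is 2.7% (the magnitude of the apo Asn66 pocket gate),
from three replicate synthetic trajectories of 10,000 frames:

```python
import flexprobe as fp
from flexprobe.synthetic_data import (
    TwoStateModel, generate_two_state_trajectory, default_chi1_references,
)

estimates = []
for seed in (1, 2, 3):
    model = TwoStateModel(p_open=0.027, seed=seed)
    traj, manifest = generate_two_state_trajectory(model, 10_000)
    labels = fp.classify_trajectory(traj, default_chi1_references(model))
    pop = fp.populations(labels, bl_state="open")
    est = fp.delta_g_bl(pop)
    estimates.append(est)
    print(f"replicate {seed}: n_open={pop.n_bl:4d}  n_closed={pop.n_nbl:5d}  "
          f"dG_open = {est.dg_kbt:+.2f} kBT")

agg = fp.aggregate_replicates(estimates)
print(f"aggregate: dG_open = {agg.dg_kbt:.2f} ± {agg.sd_kbt:.2f} kBT "
      f"(n={agg.n_replicates})")
print(f"open:closed ratio = 1 : {fp.population_ratio_from_dg(-agg.dg_kbt, 'BL'):.0f}")
```

prints

```
replicate 1: n_open= 206  n_closed= 9794  dG_open = +3.86 kBT
replicate 2: n_open= 327  n_closed= 9673  dG_open = +3.39 kBT
replicate 3: n_open= 310  n_closed= 9690  dG_open = +3.44 kBT
aggregate: dG_open = 3.56 ± 0.26 kBT (n=3)
open:closed ratio = 1 : 35
```

The aggregate recovers ln((1 − 0.027)/0.027) ≈ 3.58 k_BT: the open state
sits about 3.6 k_BT above the closed state, i.e. roughly one frame in
thirty-six is open at equilibrium.

A command-line interface mirrors the library (`flexprobe simulate`,
`classify`, `deltag`, `occlusion`, `hbonds`, `distance`, and a
config-driven `flexprobe run --config analysis.toml` that writes the ΔG,
chronology and occlusion reports with provenance headers).

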