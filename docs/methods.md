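# Methods

## The model

A flexible receptor interface is reduced to binary order parameters on a
few gate side chains.  Each trajectory frame is labelled *open* or
*closed* per residue, by one of two classifiers:

- **RMSD classifier.**  The residue's side-chain heavy atoms are compared
  with two reference conformations (an open and a closed one, e.g. from a
  ligand-bound cocrystal and an apo NMR model placed in a common
  coordinate frame); the label of the reference with the smaller RMSD
  wins.  If the references carry core coordinates, the frame is first
  rigidly fitted (Kabsch, proper rotation enforced) onto that core — the
  default core is the backbone of the stable β-sheet residues 50–55,
  80–81, 96–98, 106–109 and 120–122, which barely move across the apo
  ensemble — so that genuine side-chain displacement is measured rather
  than global drift.  Hydrogens are never used: the references are
  heavy-atom models.
- **χ1 classifier.**  The residue's first side-chain dihedral
  (N–CA–CB–X, standard atan2 sign convention; X is CG1 for Ile/Val, OG1
  for Thr, OG for Ser, SG for Cys, CG otherwise) is compared with two
  reference angles; the smaller circular distance wins.  The metric is
  periodic, so labels are invariant under ±360° shifts.

Exact ties in either classifier resolve to *closed*, the dominant apo
state — a deterministic, documented rule for a measure-zero event.

Combining the two labels assigns each frame an interface macrostate:
(closed, open) → non-bound-like (NBL); (open, closed) → PD-L1-like
bound (BL_PDL1); (open, open) → PD-L2-like bound (BL_PDL2).  The fourth
combination (closed, closed) is not an observed binding-relevant state
and is labelled `unassigned`; such frames are excluded from population
counts.

### Free energies from populations

With equilibrium populations n_BL and n_NBL of the bound-like and
non-bound-like states,

    n_BL / n_NBL = exp(−ΔG_BL / k_BT),   ΔG_BL = −ln(n_BL / n_NBL),

in units of k_BT at T = 300 K (k_B·300 K = 0.5961 kcal/mol for
conversion).  ΔG_open relates to ΔG_BL by a sign convention per
residue/ligand pairing: identical where the bound-like state is open
(Asn66 with either ligand; Ile126 with PD-L2), negated where it is
closed (Ile126 with PD-L1).  The conversion is an involution.

Replicates are aggregated by averaging ΔG values (not population ratios)
and reporting the sample SD (n−1 denominator).  Averaging ratios instead
gives a systematically different number (Jensen's inequality); the tests
document this gap explicitly.  If a state is never observed in a finite
replicate, a Jeffreys-style pseudocount of 0.5 is added to both counts
(with a warning) to keep ΔG finite; frames are otherwise treated as
samples without statistical-inefficiency reweighting, matching the
populations-from-frames procedure the analysis reproduces.

### Occlusion

A reference atom (static position + vdW radius) is *overlapped* in a
frame when any probe atom sits strictly inside the clash radius — the
sum of the vdW radii (Bondi 1964 table, overridable).  Boundary contact
is not overlap.  Probes default to all heavy atoms; hydrogens are
excluded for comparability with crystal/NMR references.  The per-atom
fractional occlusion is the overlapped-frame count divided by the frame
count; the per-frame occluded-atom count series is the cavity-formation
readout.  Candidate pairs are pruned with a k-d tree at the maximum
possible clash radius and then checked exactly, so results are identical
to the naive double loop (asserted against it in the tests).

### Hydrogen-bond chronology

A bond is present when the donor–acceptor heavy-atom distance is ≤3.5 Å
and, if an explicit hydrogen is named, the donor–H–acceptor angle is
≥135° — conventional MD criteria, both configurable per bond.  *Stable
formation* is the first present frame inside the first window of 1 ns
whose occupancy reaches 80%; a single-frame blip therefore never counts,
while a bond present throughout forms at t = 0.  (Anchoring the time to
the first present frame of the qualifying window, rather than the window
start, makes the reported time the moment the bond actually forms and
keeps it independent of the window length for clean step-like series.)
Chronologies report Δt = t(bond) − t(reference bond) per replicate,
aggregated as mean ± SD over the replicates in which the bond formed;
never-formed bonds are reported as absent with their count.  The
reference event is the formation of the key anchor hydrogen bond, which
in the intended use is the earliest interaction, so Δt ≥ 0; the
arithmetic is reported as-is if a bond precedes the reference.
Water-mediated bridges (donor–water–acceptor, distance criterion per
leg, any single water) are supported but flagged experimental.

## Synthetic data: what it emulates and what it does not

The two-state generator drives one residue's side chain between an open
and a closed ideal-geometry template (χ1 wells at −60° and 180°,
~120° apart) with a first-order Markov chain: switching attempt rate k
per frame, transition probabilities P(closed→open) = k·p_open and
P(open→closed) = k·(1 − p_open), giving stationary distribution exactly
(p_open, 1 − p_open) and lag-1 autocorrelation 1 − k.  Isotropic
Gaussian noise (σ = 0.1 Å default) is added to every atom; a high-noise
mode (σ = 0.5 Å) stresses the classifiers.  Defaults: k = 0.2,
0.1 ns/frame.  All randomness flows from a single seed, and each fixture
ships a manifest with the hidden states, so expected pipeline outputs
are recomputable exactly.

The templates are synthetic ideal-geometry Asn/Ile fragments, not
crystal coordinates; real reference conformations (apo NMR model,
ligand-bound cocrystals) are user-supplied inputs.  The generator makes
no claim to physical kinetics, solvent, correlated multi-residue motion,
or backbone flexibility: passing tests demonstrate that the estimators
recover known populations, schedules and geometries, not that any
particular receptor behaves this way.  Statistical checks on Markov
fixtures use the binomial standard error inflated by the chain's
statistical inefficiency (2 − k)/k, since successive frames are
correlated by construction.

Scheduled fixtures place a probe atom inside/outside a reference clash
radius in an exact, deterministic fraction of frames (seed affects only
approach directions), and move a donor/acceptor pair from 6.0 Å to
2.9 Å (with a collinear hydrogen) at a prescribed frame.

## Numerical choices

- Multi-model PDB is the canonical trajectory dialect: textual,
  engine-agnostic, diffable.  Coordinates serialize at `%8.3f`, so
  read∘write is identity to 1e-3 Å.  Atom counts must match across
  models (hard error naming the model); elements come from the element
  column, else from the atom name (two-character symbols CL/BR/NA/MG/
  ZN/FE/SE matched first).  The save interval is not stored in PDB and
  is a required user input — it is never guessed.
- Selections are deterministic and order-stable (chain, residue number,
  input order); backbone = {N, CA, C, O}, side-chain-heavy = heavy
  atoms excluding backbone.
- Superposition requires ≥3 non-collinear points and errors on
  degenerate geometry; the returned rotation always has det = +1.
- Rolling averages are centred in time (frames within window/2 of the
  centre frame) with truncated edges and no padding; default window
  5 ns, exposed as a parameter.  A one-frame window is the identity.
- Rotamer histograms bin the periodic square (−180°, 180°]²; counts sum
  to the frame count exactly.
- Reports format ΔG and SD to 2 decimals and times to 1 decimal, and
  embed the config hash and package version, so reruns are
  byte-identical.

## Problem sizes

The statistical tests use three replicates of 10,000 frames per
equilibrium probability p_open ∈ {0.027, 0.1, 0.5, 0.9} — enough that
the propagated standard error of ΔG is well below the 0.1–0.3 k_BT
level at the most extreme populations, spanning the 0–4.4 k_BT range of
interest.  Oracle-equivalence checks use 100 random frames with up to
100 probe and 20 reference atoms.

## Known limitations

- Two states per residue only; no automatic rotamer-library assignment.
- No periodic-boundary imaging: inputs are assumed whole solute
  molecules.
- No MBAR/WHAM reweighting or kinetic rate estimation; populations are
  raw frame counts.
- Water-mediated bond detection scans all waters per frame (O(n_water))
  and uses distance-only legs.
- mmCIF and binary trajectory formats (DCD/XTC) are not read; convert
  to multi-model PDB first.
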