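# Methods

This note defines the models implemented in `hfqtail`, the numerical
conventions, and the limits of the synthetic generators.

## 1. Ensembles and selections

An ensemble is a multi-model PDB of a hexamer (chains A–F) whose
disordered C-terminal tails vary between models.  Each model carries a
total energy, read from `REMARK 250 MODEL_ENERGY <id> <value>` lines or
from a `model_id,energy` sidecar CSV; models without an energy are a
hard error because the low-energy subset is defined by them.

Residue selections per species are shipped in
`src/hfqtail/data/selections.yaml`:

- 𝒞 — core residues (the folded Sm domain, e.g. 1–65 for *E. coli*);
- ℬ ⊆ 𝒞 — the basic patch (rim/NTD arginines and lysines);
- 𝒯 — the acidic tail-tip residues.

For *S. aureus* the curated tail set overlaps the core range (residue
65 appears in both).  The package accepts this and emits a warning
rather than rejecting the entry: the curation is taken as authoritative
over the nominal disjointness of the two sets.

Per-residue solvent-accessible surface area uses the Shrake–Rupley
algorithm (biotite backend, single-atom radii, carbon 1.7 Å, water
probe 1.4 Å) summed over a residue's atoms and averaged across chains.
Residues with SASA strictly below a cutoff (default 2.0 Å²) can be
flagged buried and excluded from the off-target set; whether burial
exclusion changes conclusions is left to the user (default: off).

## 2. Surrogate pair potential

When no external pair-energy table is given, residue–residue energies
are computed from a deliberately simple surrogate with formal side-chain
charges (Asp/Glu −1, Arg/Lys +1, all else 0), evaluated between
side-chain centroids (Cα for glycine/bead models):

```
E(r) = k·q_x·q_y / (s·r_el²) + c·max(0, r_rep − r)²
```

with k = 332 (kcal·Å/mol·e² Coulomb constant), distance-dependent
dielectric slope s = 4, soft-sphere repulsion radius r_rep = 3.0 Å and
strength c = 10.0.  Two regularizations bound the potential:

- **short-range saturation**: the electrostatic term is evaluated at
  r_el = max(r, 4.0 Å), so an oppositely charged contact is bounded
  near −5.2 energy units instead of diverging as r → 0 (the calibration
  intent is salt-bridge contacts of roughly −2 to −4);
- **long-range cutoff**: E = 0 beyond 20 Å, so well-separated residues
  contribute exactly nothing.

A ±1 pair at 5 Å scores −3.32; the potential crosses the favorability
threshold of −1.0 near 9.1 Å.  For each (model, subunit, core residue,
tail residue) the scorer takes the minimum energy over all chains
carrying the core residue (a tail may reach an adjacent subunit) and
stores only strictly negative entries.  The scale mimics Rosetta energy
units in magnitude but is not a physical force field; it exists so the
statistics pipeline can run end-to-end and be validated against planted
ground truth.

## 3. Interaction statistics (EEC / ΔEEC)

Let M be the number of models analyzed, S = 6 subunits, and let a pair
record qualify when E < −1.0 (strict).  For a core residue x:

- mean contact count ⟨N_x⟩ = (number of qualifying records involving
  x) / (S·M);
- mean energy ⟨E_x:T⟩ = (sum of qualifying energies involving x) /
  (S·M); σ_E is the population standard deviation of the per-(model,
  subunit) summed qualifying energy around that mean, with empty cells
  counted as zeros;
- σ_N is the bootstrap standard deviation of ⟨N_x⟩ over B = 1000
  resamples-with-replacement of the model set (seeded; the per-residue
  stream is derived from `SeedSequence([seed, x])` so results do not
  depend on evaluation order).

Two counting conventions are provided.  The default, `as-printed`,
counts every qualifying (core, tail-residue) pair, so one tail touching
a core residue with two tip residues counts twice.  `binary` counts at
most one contact per (model, subunit).  The default follows the summed
form of the count definition; the alternative is retained because the
two differ whenever several tail residues engage the same core residue
simultaneously.

The Expected Energetic Contribution of a residue set R is
`EEC(R) = Σ_{x∈R} ⟨N_x⟩·⟨E_x:T⟩`, with per-residue variance
σ_E²σ_N² + σ_E²⟨N⟩² + σ_N²⟨E⟩² and variances summed across residues.
`ΔEEC = EEC(ℬ) − EEC(𝒞∖ℬ)`: more negative means the tail's favorable
contacts concentrate on the basic patch rather than the rest of the
core.  By default the analysis keeps the lowest-energy
max(1, ⌊0.01·M⌋) models (ties broken by model id).

## 4. Local concentration of a tethered tip

The effective concentration of a tail tip tethered to the core is

```
C = 1 / ((V_tail − V_core) · N_A)
```

with V_tail a sphere whose radius is the tail's reach and V_core the
hexamer cylinder (radius 31.5 Å, height 25 Å), N_A = 6.02214×10²³ and
1 Å³ = 10⁻²⁷ L.  Reach estimates treat the disordered linker as a chain
of 35 Å statistical segments (~10 residues each): a full-length tail
reaches ~105 Å (C ≈ 348 μM ≈ 350 μM at 2 s.f.), a shortened linker
~70 Å (C ≈ 1222 μM ≈ 1220 μM at 3 s.f.).  The sphere-minus-cylinder
geometry ignores excluded volume of the tail itself and treats the tip
as uniformly distributed, so the value is an order-of-magnitude
estimate, not a thermodynamic quantity.

## 5. Binding models

- Single-site isotherm `y = K_a·x/(1 + K_a·x)`; K_d = 1/K_a with
  delta-method standard error.
- Hill equation `y = xⁿ/(K_dⁿ + xⁿ)` with optionally fixed n.
- Competition `y = minY + (maxY − minY)/(1 + (x/IC50)ⁿ)`; an increasing
  signal is a fit error, not a fit.
- Progress curves `y = A(1 − e^{−kt}) + c` (single) or the two-rate sum
  (double, `k_obs` = rate of the larger-amplitude phase).

All fits use `scipy.optimize.curve_fit` (trust-region reflective, with
bounds) from several starting points, keeping the lowest residual sum
of squares; a signal without curvature raises instead of returning a
meaningless estimate.  Reported per-parameter standard errors and 95%
confidence intervals come from the fit covariance.

Derived quantities:

- `K_rel = K_d(product)/K_d(substrate)`, rounded half-up to one decimal
  using exact decimal arithmetic (so 45.5/20.0 = 2.275 → 2.3); mixed
  units are an error.
- `ΔΔG° = −RT·ln(K_d,mut/K_d,wt)` with R = 1.987×10⁻³ kcal/(mol·K) and
  T = 303.15 K by default.

### Anisotropy deconvolution

At the end of an annealing reaction a labeled duplex distributes over
three states — released (χ_dr), ternary complex on Hfq (χ_hdr), and
Hfq-bound duplex (χ_hd) — whose anisotropies are r_Mdr, r_Mhdr and
r_hd.  With the constraint χ_hd = K_rel·χ_hdr and χ's summing to 1, the
measured endpoint anisotropy r_AP gives

```
χ_hdr = (r_AP − r_Mdr) / (r_Mhdr + K_rel·r_hd − (1 + K_rel)·r_Mdr)
χ_hd  = K_rel·χ_hdr
χ_dr  = 1 − χ_hdr − χ_hd
```

The denominator uses the bound-duplex anisotropy r_hd directly; this is
the algebraically consistent form (the noiseless round trip through the
mixing equation recovers the generating fractions to 1e−12, which is
enforced by an acceptance test).  A vanishing denominator (degenerate
anisotropies) raises; fractions outside [0, 1] warn, since they signal
inconsistent inputs rather than an arithmetic failure.

## 6. Synthetic generators and their fidelity limits

The bead hexamer (`ToyHexamerSpec`) is a stand-in for full-atom
disordered-tail sampling, not a model of Hfq: six rigid 12-bead cores
on a 30 Å ring, each with three +1 beads (residues 3, 5, 7) and one −1
bead (residue 9), plus a freely jointed 12-bead tail (bond 3.8 Å)
grafted at the rim.  Tails equilibrate by Metropolis pivot moves under
the same surrogate potential the scorer uses, at kT = 1.  The last four
tail beads default to charge −1 (the acidic tip); setting them to 0
gives the neutralized control.  What the generator is good for:
producing seeded, reproducible ensembles with a *tunable and known*
tail-tip/core contact propensity, so the statistics pipeline can be
validated for sign, specificity and determinism.  What it cannot do:
reproduce full-atom ensemble magnitudes (its ΔEEC values are tens of
units because the toy geometry concentrates contacts; no comparability
of magnitudes to full-atom ensembles is claimed), model sequence beyond
formal charge, or capture tail–tail interactions (each tail samples
against the cores only, independently of the other tails).

Ensemble sizes and move counts used in tests (4–20 models, 40–200
moves per residue) are scaled down for desk-scale runtimes; they are a
package choice, and the generator accepts arbitrary sizes.

Tabular generators (titration, competition, release endpoint, progress
curve) draw i.i.d. Gaussian noise around the exact model and record the
true parameters alongside the data, enabling parameter-recovery tests.

## 7. Numerical conventions

- Favorability threshold: strict `E < −1.0` (an energy of exactly −1.0
  does not count).
- Normalization of ⟨N⟩ and ⟨E⟩: always by S·M (zeros included), never
  by the number of qualifying cells.
- Population (ddof = 0) standard deviations for σ_E and the bootstrap.
- Significant-figure rounding via decimal exponent arithmetic;
  K_rel rounding via `decimal.Decimal` half-up.
- All random draws go through `numpy.random.default_rng` with explicit
  seeds; reports embed their configuration and serialize with sorted
  keys so identical inputs give byte-identical outputs.
- PDB coordinates are written with three decimals, so a round trip
  preserves coordinates to 1e−3 Å and derived energies to ~1e−4.

## 8. Limitations

- The surrogate potential is electrostatics-only; hydrophobic or
  shape-complementary contacts are invisible to it.
- SASA-based burial uses a single conformation (the lowest-energy
  model) of the rigid core.
- The concentration model ignores chain statistics beyond reach and
  treats the tip distribution as uniform.
- The deconvolution assumes exactly three states with known, distinct
  reference anisotropies and a known K_rel.
- No claim is made that toy-ensemble EEC magnitudes transfer to
  full-atom ensembles; only signs, orderings and exact-statistics
  properties are asserted.
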