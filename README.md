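# hfqtail

Quantitative analysis of how an acidic, intrinsically disordered
C-terminal tail (CTD) autoregulates the bacterial RNA chaperone Hfq.

Hfq is a homohexameric Sm-family protein whose ring carries basic
rim/N-terminal residues (arginines and lysines) that bind RNA
backbones.  Each subunit also carries a disordered C-terminal tail
ending in acidic residues.  The hypothesis this package quantifies is
that the acidic tail tips transiently dock onto the basic rim patch,
competing with RNA and thereby auto-inhibiting the chaperone.  The
package provides:

- **Interaction statistics for conformational ensembles** — per-residue
  mean contact counts ⟨N_x⟩ and mean interaction energies ⟨E_x:T⟩
  between tail residues and core residues, combined into the Expected
  Energetic Contribution `EEC = Σ_x ⟨N_x⟩·⟨E_x:T⟩` and its on-target
  minus off-target contrast ΔEEC, with bootstrap and propagated
  uncertainties (`interaction_stats`).
- **A surrogate pair potential** (screened Coulomb with short-range
  saturation and soft-sphere repulsion, in Rosetta-energy-unit-like
  magnitudes) used to score ensembles when full-atom scores are not
  provided, plus loading of externally computed pair-energy tables
  (`surrogate_energy`).
- **Ensemble I/O** — multi-model PDB reading/writing with per-model
  energies, curated residue selections (core 𝒞, basic patch ℬ, tail
  tip 𝒯) for five bacterial species, and per-residue solvent-accessible
  surface area for burial filtering (`ensemble_io`).
- **A tethered-polymer concentration model** — the effective local
  concentration of a tail tip confined to a sphere around the hexamer
  core (`polymer_model`).
- **Binding analysis** — single-site, Hill, IC50 and exponential
  progress-curve fits; K_rel, ΔΔG° and the three-state anisotropy
  deconvolution into released / ternary / binary molar fractions
  (`binding_fits`).
- **Synthetic data generators with known ground truth** — a
  coarse-grained Monte Carlo bead-hexamer whose tail-tip charges are
  tunable, and noisy titration/competition/kinetics datasets
  (`synthetic_data`).
- A `hfqtail` command-line interface and a reproducible `eec` pipeline
  that emits JSON/CSV reports (`cli`, `pipeline`).

See [docs/methods.md](docs/methods.md) for the model definitions,
conventions and limitations.

## Worked example

Generate a 20-model coarse-grained hexamer ensemble whose four acidic
tail-tip residues are attracted to the three basic core beads, then run
the full interaction analysis:

```bash
hfqtail simulate ensemble --seed 42 --n-models 20 \
    --moves-per-residue 200 --out toy.pdb
hfqtail eec toy.pdb --species toy --fraction 1.0 --seed 0
```

The second command prints a JSON report. With the commands above it
contains 1279 favorable pair records and the summary

```
ΔEEC = −41.85 ± 16.55      (on-target −41.85, off-target 0.00)
```

with per-residue statistics for the basic beads (residues 3, 5, 7):

| residue | ⟨N_x⟩ | σ_N (bootstrap) | ⟨E_x:T⟩ | σ_E |
|--------:|------:|----------------:|--------:|----:|
| 3 | 2.72 | 0.081 | −7.71 | 3.88 |
| 5 | 1.99 | 0.125 | −6.44 | 5.18 |
| 7 | 1.67 | 0.088 | −4.85 | 4.43 |

All other core residues have zero qualifying contacts, so the entire
signal is on-target: the acidic tips dock specifically onto the basic
patch.  Re-running with `--neutral-tip` produces zero favorable records
and ΔEEC = 0 — neutralizing the tip abolishes the interaction.

Scalar calculations run the same way:

```bash
$ hfqtail localconc --r-tail 105
{ "concentration_uM": 348.04…, "concentration_uM_2sf": 350.0, … }

$ hfqtail krel --kd-product 117 --kd-substrate 15.5
{ "K_rel": 7.5 }

$ hfqtail fractions --r-ap 0.0732 --r-mdr 0.0400 --r-mhdr 0.2227 \
      --r-mhd 0.2195 --r-hd 0.1332 --k-rel 7.5
{ "chi_dr": 0.680…, "chi_hd": 0.282…, "chi_hdr": 0.037… }
```

The first shows that a tail tip tethered within a 105 Å sphere around
the 31.5 × 25 Å core cylinder has an effective local concentration of
~348 μM (≈ 350 μM at two significant figures); shortening the linker to
a 70 Å reach raises this to ~1222 μM.  The last deconvolves an endpoint
anisotropy of 0.0732 into 68% released duplex, 28% Hfq-bound duplex and
4% ternary complex — most of the annealed product is released.

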