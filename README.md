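# rdcens

Replica-averaged RDC-restrained ensemble sampling and free-energy landscape
analysis for two-domain protein breathing motions.

## The problem

Enzymes that bind and release ligands often do so through sparsely populated
intermediate conformations — states with populations of a few percent that
are invisible to crystallography and to ensemble-averaged spectra alone.
Residual dipolar couplings (RDCs), measured by weakly aligning a protein in
an anisotropic medium, encode the average orientation of individual bond
vectors and are exquisitely sensitive to interdomain motion. Imposed as
*replica-averaged* restraints on a simulated ensemble, they yield — by the
maximum-entropy principle — the least-biased conformational ensemble
compatible with the measurements, from which the population of a minor
"unlocked" state can be read off a free-energy surface.

`rdcens` implements that pipeline at desk scale for researchers who want a
fully testable, ground-truth-verifiable version of the method: every stage
from alignment-tensor prediction to basin populations, plus a synthetic
two-state data generator that makes the whole loop falsifiable.

## The model

For a bond with unit vector **u** and alignment tensor **A** (symmetric,
traceless), the coupling is `D = D_max Σ_ij A_ij u_i u_j`. The restraint on
M simultaneously simulated replicas is

    E_tot = Σ_m E_pot(replica m) + α Σ_i (D_exp,i − D̄_calc,i)²,
    D̄_calc = (1/M) Σ_m D_m,

sampled by Metropolis Monte Carlo through a simulated-annealing protocol
(cycles between 310 and 500 K, restraint weight α ramped during
equilibration, frames collected in the cold window of the final cycles).
Tensors are predicted from molecular shape and charge with a planar-
obstruction model; an SVD fit is included as an independent oracle.
Ensembles are analysed through the breathing angle θ (three-region
centre-of-mass construction), RMSD after superposition, free-energy surfaces
−k_B T ln H(θ, RMSD), basin populations, and independent NMR validation
(Q factors, HNHA ³J scalar-coupling extraction via
I_X/I_D = −tan²(2πξ·³J), NOE satisfaction). See `docs/methods.md` for the
full account.

## Worked example

Python — the closed loop (generate two-state data, sample under restraints,
measure the minor population):

```python
from rdcens.workflow import recover_minor_population

r = recover_minor_population(seed=1)
print(f"recovered {r.minor_population:.3f}  truth {r.true_minor_population:.3f}")
print(r.basin_summary.to_string(index=False))
```

```
recovered 0.183  truth 0.155
   basin  fraction  n_frames  theta_mean  theta_mode
unlocked  0.183333       176   48.890056        48.5
  locked  0.816667       784   58.001464        58.5
```

The generator drew 15.5% of its 200 data frames from the minor basin; the
restrained 16-replica ensemble, started entirely from the ground state,
recovers an 18.3% unlocked population with the two basins centred at 48.9°
and 58.0° — the restraints, not the force field, created the minor basin.

Shell — the same loop via the CLI:

```sh
rdcens simulate --out-dir data --n-frames 60 --seed 3
rdcens sample --rdc-table data/rdc.tsv --out-ensemble refined.pdb \
              --replicas 8 --cycles 6 --seed 3
rdcens landscape --ensemble refined.pdb --out-grid grid.tsv \
                 --out-basins basins.tsv --seed 3
rdcens validate --ensemble data/ensemble.pdb --rdc-table data/rdc.tsv \
                --hnha-table data/hnha.tsv --noe-table data/noe.tsv \
                --out report.tsv --seed 3
```

```
collected 480 frames; acceptance 0.35; alpha 10
   basin  fraction  n_frames  theta_mean  theta_mode  rmsd_mean
unlocked  0.116667        56   48.961855        49.5   2.482164
  locked  0.883333       424   57.955606        58.5   0.149000
ensemble validation
  Q (steric): 0.057
  Q (electrostatic): 0.051
  Q (pooled): 0.054
  3J RMSD: 0.140 Hz
  NOE satisfied/violated: 93.5% / 6.5%
```

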