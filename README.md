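# memshadow

Trajectory-analysis toolkit for coarse-grained simulations of
nanoparticles in multicomponent lipid membranes: where in the membrane
plane do hydrophobic nanoparticles (e.g. C60 fullerenes) sit relative to
each lipid species, how strongly do they aggregate, and how deep is the
free-energy well that holds them in the bilayer?

It is written for simulators who have (or plan) coarse-grained membrane
trajectories and want quantitative, testable versions of the standard
qualitative analyses. Because published membrane–fullerene trajectories
are generally not deposited, the package ships a synthetic-membrane
generator that plants every structural feature the analyses measure, so
each estimator is validated by parameter recovery against known ground
truth.

## What it computes

**Shadow-matrix MSE co-localization.** The lateral plane is gridded
(0.5 nm cells); a species' *shadow matrix* for one frame is binary cell
occupancy (1 = at least one bead in the cell, both leaflets pooled). Two
species are compared by the mean square error between their shadows,

    MSE(A, B) = (1 / n_cells) * Σ (A_ij − B_ij)²,

which for binary matrices is the fraction of mismatched cells: 0 means
identical lateral localization. Ranking all lipid-tail species by mean MSE
against the nanoparticle reference, ascending, gives the co-localization
table; the lowest entries are the tails the nanoparticles live with.

**Leaflet-resolved structure.** Leaflet assignment against a local
(cell-wise, leaflet-aware) midplane; z-density profiles in the
bilayer-center frame; 2D lateral enrichment/depletion maps (local density
over lateral mean, mean ≡ 1); local thickness maps (outer minus inner
phosphate plane per cell); undulation RMS and cosine-mode spectra;
per-leaflet tail-unsaturation histograms.

**Aggregation.** Single-linkage clusters at a minimum-image contact
cutoff (default 1.0 nm), with per-frame aggregate counts and
largest-cluster fractions.

**Free energy.** A self-consistent WHAM estimator for 1D umbrella
sampling along the membrane normal, with within-window bootstrap
confidence bands and minimum depth/position extraction:

    P(z) = Σ_i n_i(z) / Σ_i N_i exp[(f_i − U_i(z))/kT],
    f_i  = −kT ln Σ_z P(z) exp(−U_i(z)/kT),      G(z) = −kT ln P(z).

## Worked example

```python
from memshadow import (MembraneSpec, build_membrane, colocalization_table)
from memshadow.colocalization import default_targets
from memshadow.trajectory_io import residue_bead_labels

spec = MembraneSpec(seed=0)           # 40x40 nm, ~6200 lipids, 30% sterol,
traj, truth = build_membrane(spec)    # 314 NPs planted onto DA-tail domains
table = colocalization_table(
    traj,
    residue_bead_labels(traj[0], "NP"),
    default_targets(spec.composition, traj[0]),
)
print(table[["species", "mean_mse", "rank"]].head(3))
```

Running the numbered drivers under `analysis/` on this system prints,
among others:

```
enrichment-map correlation NP vs DA: r = +0.631
enrichment-map correlation NP vs CHOL: r = -0.723
thickness: mean 4.001 nm over 1563 covered cells (planted plane separation 4.0 nm)
rms undulation 0.365 nm; top modes:
  k = (0, 1): amplitude 0.298 nm (planted 0.30 nm)
```

i.e. the nanoparticle enrichment map tracks the planted polyunsaturated
(DA) domains and avoids the sterol, the thickness map reproduces the
planted 4 nm phosphate-plane separation, and the undulation spectrum
recovers the planted 0.3 nm cosine modes. In the ranked MSE table the
sterol — planted anti-correlated with the nanoparticle domains — ranks
last by a wide margin, and in abundance-controlled compositions the
planted target tail ranks first in 20/20 seeds.

The same system can be analyzed from the shell:

```bash
memshadow generate --out membrane.gro --seed 0
memshadow colocal --traj membrane.gro --composition membrane.gro.composition.csv \
    --reference NP --grid-spacing 0.5 --out table.csv
memshadow run config.yaml        # full pipeline from a YAML config
```

## Layout

- `src/memshadow/` — the library (I/O, generator, colocalization,
  density/structure, clustering, WHAM, pipeline, CLI, experiments)
- `analysis/` — numbered narrative drivers writing tables to `results/`
- `tests/` — pytest suite, including planted-recovery acceptance checks
- `scratch/` — large generated coordinate files (not tracked)
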