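# idpens

Ensemble characterization for intrinsically disordered proteins (IDPs).

Unbound IDPs are not random coils: they interconvert between extended and
collapsed conformations, transiently populate local helices, and stabilize
compact states through networks of (mostly electrostatic) intramolecular
contacts.  Quantifying that heterogeneity from a conformational ensemble —
typically molecular-dynamics snapshots, here also synthetic ensembles with
known ground truth — takes a chain of analyses that `idpens` implements as
one tested toolkit:

- **Essential dynamics** — PCA of the (optionally mass-weighted)
  covariance **C** of positional fluctuations; subspace convergence
  between ensembles by the root mean square inner product,
  RMSIP = √((1/D) Σᵢⱼ (ηᵢᴬ·ηⱼᴮ)²) over the first D eigenvectors.
- **Free-energy landscapes** — G(q,p) = −kT ln P(q,p) over two reaction
  coordinates (e.g. PC1/PC2), with steepest-descent + watershed basin
  decomposition and per-frame basin membership.
- **Conformational heterogeneity** — Gromos clustering on the pairwise
  RMSD matrix, and the ensemble order parameter
  O = Σᵢ wᵢ log₂[1 + Σⱼ wⱼ exp(−D²(sᵢ,sⱼ)/2⟨D²⟩)],
  which is 1 for a single conformation and → 0 for an unboundedly
  heterogeneous ensemble (D² = squared Cα RMSD; ⟨D²⟩ = 0.27 nm² default).
- **Local structure** — Kabsch–Sander hydrogen-bond secondary structure
  (helix classes α/3₁₀/π) and Shrake–Rupley solvent-accessible surface.
- **Interaction networks** — per-class contact persistence (salt-bridge,
  aromatic, amino-aromatic, hydrophobic) as exact fractions k/F, and the
  persistence-weighted residue graph: hubs, connected components,
  exhaustive simple paths.
- **Native ESI-MS** — Gaussian deconvolution of bimodal charge-state
  distributions into conformer components with relative abundances, and a
  calibrated charge → SAS mapping.
- **Synthetic data** — a generator for helix-segment/two-state chain
  ensembles, planted contact schedules, and synthetic charge-state
  distributions, with ground-truth reports for every planted feature.

The scientific background and every numerical choice are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Generate a two-state synthetic ensemble (70 residues, two partially
occupied helical segments, 50/50 compact/extended mixture), superpose it,
and run the core analyses:

```python
from idpens import (EnsembleSpec, generate_ensemble, superpose_ensemble,
                    estimate_fel, detect_basins, assign_frames_to_basins,
                    disorder_profile)
from idpens.essential_dynamics import EssentialDynamicsPCA

spec = EnsembleSpec(
    n_residues=70,
    helical_segments=[(12, 24, 0.7), (30, 34, 0.3)],
    states=[("compact", 0.5, 1.0), ("extended", 0.5, 2.5)],
    n_frames=100,
    seed=7,
)
ensemble, truth = generate_ensemble(spec)
ensemble = superpose_ensemble(ensemble, "ca")

pca = EssentialDynamicsPCA(selection="ca").fit(ensemble)
proj = pca.transform(ensemble, 2)
print(f"variance captured by PC1+PC2: "
      f"{pca.eigenvalues_[:2].sum() / pca.total_variance_:.2f}")

fes = estimate_fel(proj[:, 0], proj[:, 1], bins=(24, 24), temperature_K=300.0)
basins = detect_basins(fes)
assign_frames_to_basins(fes, basins, proj[:, 0], proj[:, 1])
for b in basins.basins:
    if not b.minor:
        print(f"basin {b.label}: population {b.population:.2f}, "
              f"min G {b.min_g:.1f} kJ/mol")

print(disorder_profile(ensemble, (0.4, 0.5, 0.6)).to_string(index=False))
```

Output:

```
variance captured by PC1+PC2: 0.67
basin A: population 0.53, min G 0.0 kJ/mol
basin B: population 0.47, min G 0.3 kJ/mol
 cutoff_nm  n_clusters  order_parameter
       0.4          15         0.320406
       0.5          10         0.330481
       0.6           8         0.334317
```

The two major free-energy basins recover the planted compact/extended
states.  The disorder profile reads: at a 0.4 nm main-chain RMSD cutoff
the ensemble splits into 15 clusters and the order parameter O ≈ 0.32 —
far from the single-conformation value of 1, i.e. a genuinely
heterogeneous ensemble (for reference, 15 equally weighted, mutually
distant conformations would give O = log₂(1 + 1/15) ≈ 0.09; values in
between reflect the uneven cluster weights and finite inter-cluster
distances).

A command-line interface mirrors the library:

```sh
idpens simulate ensemble --seed 7 -o ens.pdb
idpens pca ens.pdb --selection ca -o pca_out
idpens fel ens.pdb --bins 24 --temp 300 -o fel_out
idpens order ens.pdb --cutoffs 0.4,0.5,0.6
idpens run --config config.json        # full pipeline, one report bundle
```

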