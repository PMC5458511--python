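# volscape

Conformational free-energy landscapes from cryo-EM 3D class ensembles.

Large flexible complexes — the motivating case is the 26S proteasome, whose
regulatory particle (RP) rotates by up to ~25° about the long axis of the
20S core particle (CP) — are routinely classified into many 3D classes, each
a density map with a particle count. `volscape` turns such an ensemble into
an energy landscape and quantifies the motion behind it:

1. **Masked rigid alignment** — every class volume is aligned to a reference
   using only the fixed subcomplex (CP), so residual differences reflect RP
   motion: the transform maximizes the masked normalized cross-correlation
   over a rotation/translation search with sub-step refinement.
2. **Eigenvolume PCA** — the aligned, masked, mean-centered volumes
   x_i are decomposed via their N×N Gram matrix; eigenvolumes
   v_k = X^T u_k / sqrt(λ_k) are orthonormal volumes and each class gets
   coefficients ("linear factors") c_ik = ⟨x_i − x̄, v_k⟩.
3. **Boltzmann inversion** — class counts n_b binned over a coefficient pair
   give free energies E_b = −ln(n_b / n_max) in units of k_BT; local minima
   and the minimax-path barrier between the two lowest minima summarize the
   landscape.
4. **Two-state particle classification** — particle images are aligned
   competitively against projection libraries of a rotated and a non-rotated
   reference and assigned by cross-correlation; three iterations of
   assignment → backprojection → low-pass/normalize yield the rotated-state
   fraction.
5. **RP rotation quantification** — the rotation angle of an aligned class
   is read off by a 1D masked rotation search about the long axis.
6. **Atomic-model metrics** — 5-residue segment B-factor classification
   (side chains < 110 Å², poly-Ala 110–150 Å², removed > 150 Å²) with model
   truncation, and inner-angle analysis of hexameric ring Cα hexagons.

A synthetic two-rigid-body phantom generator (Gaussian pseudo-atoms, seeded,
Boltzmann-distributed class counts, noisy projections) makes the entire
chain testable without any experimental data.

## Worked example

Generate a double-well ensemble (21 classes, 10^5 particles, wells at ±15°
with a 3 k_BT barrier), run the full pipeline, and inspect the landscape:

```bash
volscape simulate double_well demo --seed 1
cat > demo.yaml <<EOF
manifest: demo/manifest.tsv
reference: demo/reference.mrc
cp_mask: demo/cp_mask.mrc
pca_mask: demo/rp_mask.mrc
outdir: demo_out
seed: 1
align: {angular_range: 2.0, angular_step: 2.0, shift_range: 6.0}
landscape: {bins: 24}
EOF
volscape run demo.yaml
```

The run prints a JSON summary (numbers from an actual run with seed 1):

```json
{
  "barrier": {
    "barrier_height_kT": 2.597,
    "disconnected": false,
    "n_minima": 9
  },
  "explained_variance_fraction": [0.808, 0.165],
  "n_classes": 21,
  "total_particles": 100000
}
```

Reading it: the first eigenvolume carries ~81% of the ensemble variance —
the RP rotation is one dominant mode, with the second component (17%) being
the curvature of the rotation manifold over the ±25° arc. The occupancy
landscape over the first two coefficients shows the two ±15° wells as its
lowest minima (plus shallow discretization minima), and the lowest path
between them climbs ≈2.6 k_BT: the generator's 3 k_BT barrier minus the
broadening from the default 1-bin Gaussian smoothing. Turning smoothing off
and matching bin width to class spacing, as the quantitative tests do,
recovers 3.0 ± 0.1 k_BT. Artifacts land in `demo_out/run-<hash>/`:
aligned maps, eigenvolumes, `coefficients.tsv`, `landscape.tsv/png`,
`barrier.json`, `summary.json`.

The same CLI exposes `classify2` (two-state particle counting), `bseg` and
`ring` (atomic-model metrics) and `simulate` presets for every synthetic
condition; the library mirrors each subcommand (`volscape.align`,
`volscape.eigenvolumes`, `volscape.landscape`, `volscape.classify`,
`volscape.model_metrics`, `volscape.synthetic`). `VolumePCA` and
`TwoStateClassifier` are scikit-learn-style estimators (`fit`/`transform`,
`fit`/`predict`) if you prefer composing them directly.

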