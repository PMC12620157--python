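# slabkq

Simulation, reconstruction, and microstructure fitting for accelerated 3D
multi-slab diffusion MRI.

The package covers the full pipeline at desk scale:

- **`slabkq.protocol`** — multi-shell acquisition protocols (b-value, unit
  direction, B-tensor shape β per volume), slab geometry, scan-time
  arithmetic, and randomized 2D CAIPI (ky, kz) undersampling masks. The
  reference configuration (3 shells at b = 1000/2000/6000 s/mm², 22
  directions each, Ry = 3, Rz = 20/6, TR = 2 s, 20 × 1 mm kz encodes per
  slab) yields 12 s per diffusion volume, a 13.9 min 66-volume schedule,
  and a net undersampling factor of 10.
- **`slabkq.signal_model`** — the 3-compartment diffusion kernel
  (intra-axonal stick, extra-axonal zeppelin, free water) for linear and
  general B-tensor encodings, ODF convolution on a deterministic spherical
  quadrature, Watson and band-limited ODFs, and closed-form powder
  averages.
- **`slabkq.phantom`** — a digital multi-slab head phantom (CSF, GM, WM
  and corpus-callosum-like regions with literature parameter values),
  smooth complex coil sensitivities, raised-cosine slab profiles,
  per-shot polynomial motion phases, and the multi-coil k-space +
  low-resolution navigator simulator with calibrated noise.
- **`slabkq.dae_prior`** — a compact fully connected denoising autoencoder
  over the q-space signal manifold (numpy implementation with Adam),
  trained on simulated signals with a weighted MSE that up-weights the
  highest-b shell (weight 1.5 by default).
- **`slabkq.recon`** — phase-compensated SENSE forward/adjoint operators,
  CG-SENSE navigator phase estimation, and the joint k-q reconstruction
  minimizing `‖A(S) − Y‖² + λ₁·TV(S) + λ₂·‖S − Q(S)‖²` by half-quadratic
  splitting (denoise → CG → TV prox). λ₂ = 0 gives the ablated variant,
  λ₁ = λ₂ = 0 plain phase-compensated CG-SENSE. Includes the
  profile-weighted slab combiner.
- **`slabkq.fitting`** — compartment-parameter estimation from per-shell
  rotational invariants (spherical mean + ℓ = 2) with bounded multistart
  least squares and branch-degeneracy flagging, DTI (FA/MD) and DKI (MK)
  validation fits, and ROI mean/SD/COV statistics.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the desk-scale acceptance experiments
(undersampled reconstruction ordering, denoiser training behavior,
parameter-recovery studies); the full suite runs in roughly ten minutes
on one CPU.

## CLI

```sh
slabkq protocol build --out grad          # write bval/bvec/beta tables
slabkq protocol masks --ry 3 --rz 20/6 --seed 1 --out masks.npy
slabkq simulate --shape 32 33 6 --snr 20 --seed 1 --out scratch/sim.npz
slabkq train-dae --weight 1.5 --out dae.npz
slabkq fit --volumes dwi.nii --grad grad --out maps/
slabkq roi-stats --maps maps/ --labels labels.nii
```

## Notes

- Reconstruction-scale arrays (k-space, models) are written to scratch
  paths as `.npz`/`.npy`; parameter maps are NIfTI with JSON unit
  sidecars; gradient tables use the FSL bval/bvec layout plus a
  one-column `.beta` file.
- With linear-encoding-only shells the compartment fit has a known
  two-branch degeneracy; such voxels are flagged. Adding a spherical
  (β = 0) shell restores global identifiability and is used in the
  recovery experiments.
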