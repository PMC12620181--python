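# aquamap

Free-breathing 3D water-specific T1/T2 mapping of the abdomen, implemented
end to end in silico. Fat infiltration and respiratory motion confound
conventional abdominal relaxometry: fat protons bias T1/T2 estimates, and
breathing blurs free-running 3D acquisitions. `aquamap` implements a
quantitative MRI pipeline that addresses both, together with the digital
phantom and forward simulator needed to validate it without a scanner.

The method:

1. **Sequence + dictionary** — a four-block Look-Locker acquisition
   (3-s blocks; adiabatic mBIR-4 preparation with block-wise durations
   TPrep = 10.9/25.9/40.9/55.9 ms for T2 weighting; 7 shots x 60 profiles,
   TR 3.4 ms, dual bipolar echoes at TE 1.0/2.1 ms) is Bloch-simulated over
   a (T1, T2, B0) grid of 124 x 75 x 21 = 195 300 atoms x 1680 profile
   times.
2. **Subspace** — the first k = 5 right singular vectors Phi of the
   dictionary span the temporal signal space (>= 97% of the
   squared-singular-value energy).
3. **Sampling + soft-gating** — profiles follow a golden-step CASPR spiral
   ordering on the Cartesian ky-kz grid at R = 7.5 per contrast; a
   respiratory surrogate m[n] is clustered by k-medoids and each profile
   weighted by `w[n] = exp(-(m[n] - m_ref)^2 / (2 sigma^2))`, with
   `sigma = |m_ref2 - m_ref| / (2 sqrt(2 ln 2))`.
4. **Reconstruction** — per echo, the k coefficient images solve
   `argmin_x ||W^(1/2)(P F S x - y)||_2^2 + lambda sum_i alpha_i TV(x_i)`
   by ADMM with an FGP total-variation prox (W = density compensation x
   gating weights; S coil sensitivities; P the temporal subspace
   projection), after noise pre-whitening and bipolar echo-misalignment
   correction.
5. **Water-fat + matching** — a dual-echo graph-cut field map (multi-peak
   fat model) feeds an exact 2 x 2 water/fat solve per coefficient image;
   the water coefficients are matched against the B0-specific subdictionary
   (extended to +-300 Hz) to give wT1, wT2 and a PD-like water image.

See `docs/methods.md` for the model details and design choices.

## Worked example

Run the full synthetic validation study (digital vial phantom at
48 x 48 x 12, 3-mm voxels, R = 7.5, simulated breathing, correlated coil
noise, bipolar echo shift):

```bash
aquamap standard-study --seed 1 --out report.json
```

or equivalently from Python:

```python
from aquamap.study import standard_study
report = standard_study(seed=1).report
```

Key numbers this prints (seed 1):

```
"subspace_energy_k": 0.9997,          # basis captures 99.97% of the energy
"echo_shift": {"true": 0.35, "estimated": 0.3480},
"median_wt1_error_pct": 3.03,         # median |wT1 error| inside vials
"median_wt2_error_pct": 7.69,         # median |wT2 error| inside vials
"median_b0_error_hz": 0.0,            # graph-cut field-map accuracy
"nrmse_gated": 17.3, "nrmse_ungated": 34.9,  # soft-gating clearly helps
```

plus a per-vial table of true vs estimated wT1/wT2. The wT1/wT2 medians say
the pipeline recovers the ground-truth relaxation times of the vials to a
few percent despite 7.5-fold undersampling, breathing motion and up to 25%
fat fraction; the NRMSE pair (coefficient-image error vs ground truth,
gated vs ungated reconstruction) quantifies how much the respiratory
soft-gating improves the reconstruction.

The individual stages are also exposed as CLI subcommands
(`simulate`, `dict`, `basis`, `recon`, `waterfat`, `match`, `evaluate`)
operating on HDF5 / NIfTI files, and as library functions
(`aquamap.sequence`, `.subspace`, `.trajectory`, `.gating`, `.phantom`,
`.recon`, `.waterfat`, `.matching`, `.evaluate`, `.io`).

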