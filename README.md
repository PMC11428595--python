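# dentalid

Dental biometric identification from 3D intraoral-scan point clouds.

Teeth survive fires, crashes and immersion better than any other tissue,
which makes dentition a last-resort biometric for forensic identification.
`dentalid` implements a three-stage pipeline that matches a query scan of a
dentition against a gallery of enrolled scans:

1. **Crown-contour extraction.** Mean curvature is estimated at every point
   by pseudo-inverse quadric fitting in the local normal frame; points with
   H < −0.6 mm⁻¹ — the rolled margin where each crown meets the gingiva —
   form the feature cloud. Connected-component filtering removes noise,
   and the contour can be split into its gingival-line sectors
   (left posterior / anterior / right posterior) to study partial tooth loss.
2. **Feature description.** Centroid voxel downsampling (1 mm grid),
   then 33-bin FPFH descriptors: for each point pair the Darboux frame
   U = nₛ, V = U×(Pₜ−Pₛ)/‖·‖, W = U×V yields α = V·nₜ,
   φ = U·(Pₜ−Pₛ)/‖Pₜ−Pₛ‖, θ = atan2(W·nₜ, U·nₜ), histogrammed over 11
   bins each and aggregated over the neighbourhood with inverse-distance
   weights: FPFH(Pₛ) = SPFH(Pₛ) + (1/n)·Σᵢ (1/ωᵢ)·SPFH(Pkᵢ).
3. **Coarse-to-fine registration and identification.** SAC-IA draws random
   point triplets, matches them by FPFH similarity, fits rigid transforms
   in closed form and keeps the candidate with best (fitness, RMSE); ICP
   refines it by minimizing E(R,T) = (1/N)·Σₕ‖qₕ−(R·pₕ+T)‖². The gallery
   entry with the smallest final RMSE is the assigned identity; Rank-k
   rates and genuine/impostor statistics summarize a full experiment.

Clinical scans are private, so the package ships seeded generators for
synthetic dental arches and crown contours with per-subject shape
variation, plus a repeat-scan perturbation model (pose change, sensor
noise, dropout, regional tooth loss). Every stage is tested end-to-end on
this synthetic data; see `docs/methods.md` for what that does and does not
demonstrate.

## Worked example

Register a simulated repeat scan (new pose, σ = 0.05 mm noise, 20%
dropout) against the right and the wrong subject:

```python
from dentalid import (ArchParams, PerturbationParams, RegistrationParams,
                      generate_contour, perturb, register_coarse_to_fine)

subject_a = generate_contour(ArchParams(subject_seed=7))
subject_b = generate_contour(ArchParams(subject_seed=99))
repeat_scan, _ = perturb(subject_a, PerturbationParams(scan_seed=3))

reg = RegistrationParams(seed=1)
genuine = register_coarse_to_fine(repeat_scan, subject_a, reg=reg)
impostor = register_coarse_to_fine(repeat_scan, subject_b, reg=reg)
print(f"genuine : fitness={genuine.fitness:.4f}  rmse={genuine.rmse:.4f} mm")
print(f"impostor: fitness={impostor.fitness:.4f}  rmse={impostor.rmse:.4f} mm")
```

prints

```
genuine : fitness=1.0000  rmse=0.0794 mm
impostor: fitness=0.7649  rmse=1.2446 mm
```

The genuine pair converges to the sensor-noise floor (~0.08 mm for
σ = 0.05 mm), while the impostor pair cannot do better than the
inter-subject shape difference — an order of magnitude larger. Fitness
(fraction of points with a neighbour within 2 mm) barely separates the
two, which is why identity is assigned by minimum RMSE.

More examples live in `examples/` (one script per capability):
`extract_contour.py` (stage 1), `fpfh_descriptors.py` (stage 2, descriptor
pose-invariance), `register_pair.py` (stage 3), `identify_benchmark.py`
(a 5-subject end-to-end run: Rank-1 100%, genuine RMSE 0.078–0.080 mm vs
impostor 0.780–1.225 mm).

## Command line

```sh
dentalid simulate --out-dir bench --n-subjects 20 --seed 42   # synthetic benchmark
dentalid extract scan.ply contour.ply [--region anterior]     # stage 1
dentalid register query.ply gallery.ply --method coarse2fine  # stage 3, one pair
dentalid identify bench/queries bench/gallery --out-dir run   # full experiment
dentalid evaluate --out-dir run --n-subjects 20 --seed 42     # simulate + identify
```

`identify`/`evaluate` write RMSE and fitness score matrices (CSV + grayscale
pixmaps), a Rank-k report, and a provenance block echoing the full
configuration. All parameters are `key = value` config entries overridable
with `--set key=value`.

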