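"""Stage 3: coarse-to-fine registration of a genuine and an impostor pair.

A 'repeat scan' of subject A (new pose, sensor noise, dropout) is
registered onto subject A's gallery contour and onto subject B's.  The
genuine pair converges to the sensor noise floor; the impostor pair
cannot, and the RMSE gap is the identification signal.
"""

from dentalid import (
    ArchParams,
    PerturbationParams,
    RegistrationParams,
    generate_contour,
    perturb,
    register_coarse_to_fine,
)

subject_a = generate_contour(ArchParams(subject_seed=7))
subject_b = generate_contour(ArchParams(subject_seed=99))
repeat_scan, _ = perturb(subject_a, PerturbationParams(scan_seed=3))

reg = RegistrationParams(seed=1)
genuine = register_coarse_to_fine(repeat_scan, subject_a, reg=reg)
impostor = register_coarse_to_fine(repeat_scan, subject_b, reg=reg)

print(f"genuine : fitness={genuine.fitness:.4f}  rmse={genuine.rmse:.4f} mm "
      f"(coarse rmse {genuine.coarse.rmse:.4f})")
print(f"impostor: fitness={impostor.fitness:.4f}  rmse={impostor.rmse:.4f} mm")
print("-> genuine RMSE sits at the 0.05 mm noise floor; the impostor pair")
print("   stays an order of magnitude higher, so minimum RMSE picks the identity")
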