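"""Stage 1: extract the crown contour from a synthetic arch scan.

Generates a 4-tooth synthetic arch surface, estimates mean curvature by
quadric fitting, thresholds at -0.6 1/mm and removes small components.
The surviving points trace the gingival margin roll around each crown —
the geometry that identifies a person.
"""

from dentalid import (
    ArchParams,
    PreprocessParams,
    extract_contour,
    generate_arch,
    mean_curvature,
    remove_small_components,
)

pre = PreprocessParams()
arch = generate_arch(ArchParams(n_teeth=4, arch_width=40, arch_depth=30, subject_seed=5))
curv = mean_curvature(arch, pre.curvature_k)
contour = extract_contour(arch, curv, pre.curvature_threshold)
clean = remove_small_components(contour, pre.link_radius, pre.min_component_size)

print(f"arch surface: {len(arch)} points")
print(f"curvature < {pre.curvature_threshold} 1/mm: {len(contour)} points")
print(f"after denoising: {len(clean)} contour points")
print("-> one closed margin ring per tooth; caps and gingiva are filtered out")
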