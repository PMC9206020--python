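"""Cohort lesion overlay and per-structure damage for one subject.

Builds a synthetic 41-subject stroke cohort, flips all lesions onto the left
hemisphere, prints the overlay peak (how many subjects share the most-hit
voxel) and the percent damage of each toy-atlas structure for one subject.
"""

from lesionmap import (
    SyntheticSpec,
    generate_cohort,
    overlay_map,
    percent_damage,
    toy_atlas,
    unify_hemisphere,
)
from lesionmap.lesion_io import Cohort

cohort, _ = generate_cohort(SyntheticSpec(seed=1))
masks, flipped = unify_hemisphere(cohort.masks)
cohort = Cohort(masks=masks, scores=cohort.scores)

overlay = overlay_map(cohort)
print(f"subjects: {cohort.n_subjects}, flipped to left: {len(flipped)}")
print(f"overlay peak: {overlay.max()} subjects lesioned at the most-hit voxel")
print(f"voxels covered by >= 8 subjects (20%): {(overlay >= 8).sum()}")

atlas = toy_atlas(cohort.grid)
table = percent_damage(cohort.masks[0], atlas)
hit = table[table.percent > 0].round(1)
print(f"\nper-structure damage for {cohort.masks[0].subject_id} "
      f"(lesion {cohort.masks[0].volume_cc:.1f} cc):")
print(hit.to_string(index=False))
print("\npercent = share of each structure's voxels inside the lesion.")
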