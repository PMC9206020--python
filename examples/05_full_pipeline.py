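"""One-call end-to-end run: synth -> overlay -> VLSM x2 -> conjunction.

Writes NIfTI volumes, TSV tables, a run log and a manifest JSON into an
output directory, then prints the manifest's headline numbers.
"""

import json
import tempfile
from pathlib import Path

from lesionmap import RunConfig, run_all

out_dir = Path(tempfile.mkdtemp()) / "demo_run"
run_all(RunConfig(out_dir=str(out_dir), seed=1))

manifest = json.loads((out_dir / "manifest.json").read_text())
print(f"outputs in {out_dir}:")
for p in sorted(out_dir.iterdir()):
    print(f"  {p.name}")

print(f"\nn = {manifest['n_subjects']}, voxel coverage threshold = "
      f"{manifest['min_lesioned']} subjects, tested voxels = "
      f"{manifest['n_included_voxels']}")
print(f"paresis map: {manifest['vlsm_a']['n_significant']} FDR-significant "
      f"voxels in {manifest['vlsm_a']['n_clusters']} clusters")
print(f"lenient z* = {manifest['z_star']:.2f} ({manifest['lenient_source']})")
print(f"spasticity map: {manifest['vlsm_b']['n_significant']} voxels at z*")
print(f"conjunction: {manifest['conjunction']['counts']}")
print(f"selective fractions: paresis "
      f"{manifest['conjunction']['selective_pct_a']:.0f}%, spasticity "
      f"{manifest['conjunction']['selective_pct_b']:.0f}%")
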