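"""Full pipeline on the kidney presets: normal vs 2-week obstructed.

Builds each phantom, simulates both scan protocols, computes dB/LIV/Fast-DOCT
volumes, segments the surface, projects surface-aligned slabs, renders the
composites and prints the phenotype metrics. Outputs land in
``scratch/example_runs/<preset>/`` (TIFF volumes, PNG composites, JSON report).
"""

import json
from pathlib import Path

from doctk.pipeline import RunConfig, run

out_base = Path("scratch/example_runs")
for preset in ("normal", "obstructed_2w"):
    cfg = RunConfig(preset=preset, seed=7, log_level="WARNING")
    manifest = run(cfg, out_base / preset)
    report = json.loads((out_base / preset / "report.json").read_text())
    print(f"--- {preset} ---")
    print(f"  tubule LIV contrast ratio:  {report['tubule_liv_ratio']}")
    print(f"  shell LIV contrast ratio:   {report['shell_liv_ratio']}")
    print(f"  surface layer thickness:    {report['surface_layer_thickness_um']} um")
    print(f"  grades: {report['grades']}")
    print(f"  outputs: {len(manifest['files'])} files in {out_base / preset}")

print()
print("normal kidney: convoluted pipe-like tubules light up in LIV (ratio >= 3);")
print("obstructed kidney: tubules gone, a ~60 um high-dynamics shell hugs the surface.")
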