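#!/usr/bin/env python
"""Generate the synthetic study scene and write it to disk.

Builds the gradient scene used throughout the analysis: one fractal
terrain shared by both halves, natural land cover on the left half and a
cropland/pasture/urban mosaic on the right, with wetlands clustered on
low ground and a four-type soil mosaic.  Rasters go to scratch/scene/
(Esri ASCII grids); a small manifest with the configuration and layer
checksums goes to results/.
"""

import hashlib
import json
from pathlib import Path

import numpy as np

from resilscape.io import write_stack
from resilscape.synthetic_scene import make_gradient_scene

SEED = 0
SHAPE = (256, 256)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    stack = make_gradient_scene(shape=SHAPE, seed=SEED)
    out = ROOT / "scratch" / "scene"
    paths = write_stack(stack, out)

    manifest = {
        "seed": SEED,
        "shape": list(SHAPE),
        "cell_size_m": stack["dem"].cell_size,
        "layers": {
            name: hashlib.sha256(stack[name].values.tobytes()).hexdigest()[:16]
            for name in sorted(stack)
        },
    }
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    (results / "scene_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    dem = stack["dem"].values
    print(f"wrote {len(paths)} layers to {out}")
    print(f"DEM relief: {np.ptp(dem):.0f} m over {SHAPE[0]}x{SHAPE[1]} cells of "
          f"{stack['dem'].cell_size:.0f} m")
    print(f"wetland fraction: {stack['wetlands'].values.mean():.3f}")
    natural = np.isin(stack['lulc'].values, (1, 2, 3)).mean()
    print(f"natural cover fraction (whole scene): {natural:.3f}")


if __name__ == "__main__":
    main()
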