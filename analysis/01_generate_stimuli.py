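"""Synthesize the stimulus battery and write it to disk.

Generates the full set of study conditions -- natural-image surrogates
(1/f^k noise), band-pass bump noise, sinusoidal gratings, and stripe
textures, all Gaussian-windowed -- saves 8-bit PNGs under scratch/stimuli/
and a sidecar metadata table (filename, category, spatial frequency, ppd,
seed) under results/.
"""

import sys
from pathlib import Path

import imageio.v3 as iio
import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
from common import CFG, RESULTS, SCRATCH

from viscomfort.study import build_battery, _spatial_frequency_of


def main() -> None:
    out_dir = SCRATCH / "stimuli"
    out_dir.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)

    battery = build_battery(CFG)
    rows = []
    for image_id, img in battery:
        fname = f"{image_id}.png"
        iio.imwrite(out_dir / fname, np.rint(img.pixels * 255).astype(np.uint8))
        rows.append(
            f"{fname},{image_id},{img.category},"
            f"{_spatial_frequency_of(image_id):g},{img.ppd:g},{CFG.master_seed}"
        )
    meta = RESULTS / "stimuli_metadata.csv"
    meta.write_text(
        "filename,image_id,category,spatial_frequency,ppd,master_seed\n"
        + "\n".join(rows) + "\n"
    )
    print(f"wrote {len(battery)} stimuli ({CFG.image_size}x{CFG.image_size} px, "
          f"{CFG.ppd:g} px/deg) to {out_dir}")
    print(f"metadata -> {meta}")


if __name__ == "__main__":
    main()
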