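"""Shared configuration for the numbered analysis scripts.

One study-scale configuration: 256 px images at 32 px/deg (Nyquist
16 c/deg), the five-frequency battery used for the EEG-style conditions,
six natural-image surrogates, a 500-cell model population, and 3,000
retained edges per image for the pairwise entropy.  Every script derives
its inputs deterministically from this object, so the scripts can be run
independently or in sequence.
"""

from pathlib import Path

from viscomfort.study import StudyConfig

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

CFG = StudyConfig(
    master_seed=2026,
    image_size=256,
    ppd=32.0,
    n_cells=500,
    bump_frequencies=(0.75, 1.5, 3.0, 6.0, 9.0),
    grating_frequencies=(0.75, 1.5, 3.0, 6.0, 9.0),
    stripe_frequencies=(0.75, 1.5, 3.0, 6.0, 9.0),
    natural_exponents=(-0.85, -0.95, -1.0, -1.05, -1.1, -1.2),
    edge_top=3000,
    window_flat_px=75,
    intercept=4.0,  # centred on the 1-7 scale to keep Likert clipping rare
)
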