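"""Display geometry and shared calibration defaults.

Spatial frequencies throughout the package are in cycles per degree of
visual angle (c/deg) and are converted to cycles per pixel through a
pixels-per-degree (ppd) calibration.  The default ppd is derived from the
study display geometry -- a 22-inch 4:3 CRT at 1024x768 viewed from 1 m --
rather than hard-coded, so estimators never assume a particular monitor.
"""

from __future__ import annotations

import numpy as np

#: display resolution (width, height) in pixels
DISPLAY_RES = (1024, 768)
#: diagonal size of the display in metres (22 inches)
DISPLAY_DIAG_M = 22 * 0.0254
#: viewing distance in metres
VIEW_DIST_M = 1.0


def pixels_per_degree(
    resolution: tuple[int, int] = DISPLAY_RES,
    diag_m: float = DISPLAY_DIAG_M,
    dist_m: float = VIEW_DIST_M,
) -> float:
    """Average pixels per degree of visual angle across the display width.

    The small-angle variation across the screen is ignored; a single scalar
    calibration is used for all stimuli and estimators.
    """
    w_m = diag_m * resolution[0] / float(np.hypot(*resolution))
    width_deg = 2.0 * np.degrees(np.arctan(w_m / (2.0 * dist_m)))
    return resolution[0] / width_deg


#: default calibration used by stimulus generators (approx. 40.6 px/deg)
DEFAULT_PPD = float(pixels_per_degree())
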