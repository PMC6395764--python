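"""Recover a sub-resolution tubule radius from integrated intensity.

A 40 nm-radius tubule imaged through a 140 nm psf renders ~150 nm wide
(FWHM is psf-limited), but its *integrated* brightness scales with the
cross-sectional area.  Referencing against the known sheet intensity
I_s and thickness T_s gives r_t = sqrt((I_t/I_s) psf_xy T_s / 4).
"""

import numpy as np

from erquant.config import PsfCalibration
from erquant.segment import PixelSkeleton
from erquant.synth import generate_straight_tubule
from erquant.width import estimate_widths

cal = PsfCalibration()       # psf 140 nm, T_s 40 nm, I_s 0.35
print(f"calibration: psf_xy={cal.psf_xy_nm:.0f} nm, "
      f"T_s={cal.sheet_thickness_nm:.0f} nm, I_s={cal.sheet_ref_intensity}")

for true_radius in (15.0, 30.0, 60.0):
    stack, truth = generate_straight_tubule(radius_nm=true_radius)
    wm = estimate_widths(stack.data[0, 0],
                         PixelSkeleton(truth.skeleton[0]), cal,
                         stack.pixel_size_nm, max_radius_px=12)
    ys, xs = np.nonzero(truth.skeleton[0])
    inner = (xs > 30) & (xs < 225)
    fwhm = np.nanmedian(wm.fwhm_nm[ys[inner], xs[inner]])
    rad = np.nanmedian(wm.calibrated_radius_nm[ys[inner], xs[inner]])
    print(f"true radius {true_radius:5.1f} nm -> FWHM {fwhm:6.1f} nm "
          f"(psf-saturated), calibrated radius {rad:5.1f} nm")
print("The FWHM saturates near the psf; the calibrated radius recovers")
print("the true sub-resolution value from integrated brightness.")
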