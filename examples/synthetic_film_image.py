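"""Render a synthetic 8-field calibration film and close the loop.

Simulates one scanned calibration film: eight 3x3 cm^2 subfields at doses
16-128 cGy on a uniform background, at the 0.123 mm scanner pitch, with 1%
readout noise.  ROI means (1.23 mm square) at the subfield centres are
extracted and fitted, recovering the generating response curve from the
image alone — the complete 8-field calibration workflow in silico.
"""

from filmcal import (
    CalibrationDataset,
    CalibrationParams,
    DosePoint,
    extract_roi,
    fit_full,
    render_eightfield_image,
)

truth = CalibrationParams(245.0, 3271.0, 31.7)
img = render_eightfield_image(truth, noise=0.01, seed=4)
h, w = img.shape
print(f"rendered film: {h}x{w} px at {img.pitch} mm/px "
      f"({h*img.pitch/10:.1f} x {w*img.pitch/10:.1f} cm)")

points = []
for r, c, dose in img.subfield_layout:
    roi = extract_roi(img, (r, c), 1.23)
    points.append(DosePoint(dose, roi))
    print(f"  subfield at ({r:5.1f}, {c:5.1f}) mm, {dose:5.1f} cGy -> ROI mean {roi:7.1f}")

background = extract_roi(img, (5.0, 5.0), 12.3 / 2)
ds = CalibrationDataset(points=tuple(points), background_pixel=background)
res = fit_full(ds)
p = res.params
print(f"\nrefit from image:  P0={p.P0:.1f}  Ps={p.Ps:.1f}  m={p.m:.2f}")
print(f"generating truth:  P0={truth.P0}  Ps={truth.Ps}  m={truth.m}")
print("\nROI averaging suppresses the 1% per-pixel noise, so the fitted")
print("parameters land within a fraction of a percent of the truth.")
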