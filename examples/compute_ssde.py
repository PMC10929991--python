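"""Compute a size-specific dose estimate for one synthetic thoracic slice.

Builds a noiseless phantom with known geometry, segments it with the
HU-threshold reference segmenter, and walks the full dose chain:
class map -> body mask -> water-equivalent diameter D_w, and
class map -> AP/LAT chords -> corrected effective diameter D_eff_corr,
then SSDE = f(D) x CTDIvol for both size metrics.
"""

from ssdekit import CTSlice, PhantomSpec, compute_dose, generate_phantom

spec = PhantomSpec()  # 30 x 20 cm body, two lungs, vertebral bone, CTDIvol 8.5 mGy
hu, truth = generate_phantom(spec)
ct = CTSlice(hu_pixels=hu, pixel_spacing=spec.pixel_spacing, ctdi_vol=spec.ctdi_vol)

res = compute_dose(ct, segmenter="threshold")

print(f"analytic truth:  D_w = {truth.d_w:.2f} cm, D_eff_corr = {truth.d_eff_corr:.2f} cm")
print(f"pipeline:        D_w = {res.d_w:.2f} cm, D_eff_corr = {res.d_eff_corr:.2f} cm")
print(f"conversion factors: f(D_w) = {res.f_dw:.3f}, f(D_eff_corr) = {res.f_deff:.3f}")
print(f"SSDE_Dw   = {res.ssde_dw:.1f} mGy   (CTDIvol {spec.ctdi_vol} mGy scaled by f)")
print(f"SSDE_Deff = {res.ssde_deff:.1f} mGy")
print()
print("The SSDEs exceed CTDIvol because this body is smaller than the 32-cm")
print("reference phantom; the two size metrics differ because D_eff_corr")
print("weights lung at 0.3 and bone at 1.2 along two chords, while D_w")
print("averages attenuation over the whole cross-section.")
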