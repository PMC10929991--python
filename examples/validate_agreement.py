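"""Agreement between SSDE computed from D_eff_corr and from D_w.

Runs the threshold-segmenter pipeline over a synthetic cohort and compares
the two per-slice SSDE series with linear regression, Pearson correlation,
signed percentage differences and Bland-Altman limits of agreement.
"""

from ssdekit import CTSlice, agreement_analysis, compute_dose, generate_cohort

cohort = generate_cohort(40, seed=12, raster_shape=(240, 240),
                         pixel_spacing=(2.0, 2.0))
ssde_deff, ssde_dw = [], []
for hu, truth, spec in cohort:
    ct = CTSlice(hu_pixels=hu, pixel_spacing=spec.pixel_spacing, ctdi_vol=spec.ctdi_vol)
    res = compute_dose(ct)
    ssde_deff.append(res.ssde_deff)
    ssde_dw.append(res.ssde_dw)

rep = agreement_analysis(ssde_deff, ssde_dw)
print(f"n = {len(ssde_deff)} slices")
print(f"regression: slope {rep.slope:.3f}, intercept {rep.intercept:.3f} mGy, "
      f"R^2 {rep.r_squared:.3f}")
print(f"Pearson r = {rep.pearson_r:.3f}")
print(f"mean %diff = {rep.mean_pct_diff:+.1f}%  largest = {rep.largest_pct_diff:+.1f}%")
print(f"Bland-Altman: bias {rep.bias:+.2f} mGy, "
      f"limits of agreement [{rep.loa_low:+.2f}, {rep.loa_high:+.2f}] mGy")
print()
print("The two series track each other tightly (r near 1) but differ by a")
print("systematic offset: on these lung-dominated phantoms the chord-based")
print("electron-density correction reads D_eff_corr smaller than D_w, so its")
print("conversion factor, and hence its SSDE, is the larger of the two.")
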