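"""Per-pixel lipid/HCL/DS maps of a simulated tumor-bearing liver lobe.

Models calibrated on simulated whole lobes are applied pixel by pixel to
a scene whose embedded tumor carries more linoleic acid (lower DS) and
more total lipid than the surrounding tissue.  The region summary shows
the recovered contrast.
"""

from pathlib import Path

from nirlipid import mapping, preprocess, regress, synth

spectra, truth = synth.simulate_study(n_per_diet=8, seed=1)
cal = regress.CalibrationSet.from_spectra(spectra, truth)
models = {t: regress.fit(cal, t) for t in ("lipid", "hcl", "ds")}

scene = synth.tumor_scene(seed=7)
raw, dark, white = synth.render_cube(scene)
cube = preprocess.pixel_snv_spectra(raw, dark, white)
cube.mask &= scene.tissue_mask

rasters = {t: regress.predict_pixels(m, cube) for t, m in models.items()}
pmap = mapping.PredictionMap(rasters=rasters, mask=cube.mask)

out = Path("scratch/maps") if Path("scratch").is_dir() else Path("maps")
files = mapping.render_maps(pmap, out / "tumor", pseudo=mapping.pseudo_color(cube))
print(f"wrote {len(files)} map files under {out}/")

for region in scene.regions:
    s = mapping.summarize_region(pmap, region.mask, region.name)
    print(
        f"{s.label:>7}: n={s.n_pixels:>3}  "
        f"lipid={s.means['lipid']:6.1f} mg/g  "
        f"HCL={s.means['hcl']:.3f}  DS={s.means['ds']:.3f}"
    )
print("expected contrast: tumor DS below normal, tumor lipid above normal")
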