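"""The HCL/DS plane: diet-group means framed by the fatty-acid panel.

Every tissue composition plots inside the region spanned by its
constituent fatty acids' (HCL, DS) vertices; diet-driven shifts in the
accumulated fatty acids move the group points around that region.
"""

from pathlib import Path

from nirlipid import chem, mapping, synth

profiles = []
for name, diet in synth.default_diet_profiles().items():
    p = chem.composition_profile(diet.mean_fractions)
    profiles.append(
        chem.TissueLipidProfile(hcl=p.hcl, ds=p.ds, label=name)
    )
    print(f"{name:>5}: HCL={p.hcl:.2f}  DS={p.ds:.2f}")

points = chem.hcl_ds_scatter_data(profiles, chem.DEFAULT_PANEL)
out = Path("scratch/plots") if Path("scratch").is_dir() else Path("plots")
fig, csv = mapping.render_hcl_ds_plot(points, out / "hcl_ds.png")
print(f"\nfigure: {fig}\nplotted coordinates: {csv}")
print("x: mean chain length; y: saturation (1 = no double bonds)")
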