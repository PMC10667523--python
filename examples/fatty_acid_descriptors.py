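"""Functional-group chemistry: HCL and DS of single fatty acids and of a
tissue composition.

HCL (hydrocarbon chain length) counts all carbons per terminal methyl
group; DS (degree of saturation) is the CH2 share of the chain interior,
1 for saturated chains and lower with every C=C bond.
"""

from nirlipid import chem

for shorthand in ("16:0", "18:0", "18:1", "18:2", "18:3"):
    fa = chem.parse_fatty_acid(shorthand)
    g = chem.count_functional_groups(fa)
    print(
        f"C{shorthand:<5} CH3={g.n_ch3} CH2={g.n_ch2:>2} CH={g.n_ch:>2} "
        f"COOH={g.n_cooh}  HCL={chem.fatty_acid_hcl(fa):.0f}  "
        f"DS={chem.round_half_up(chem.fatty_acid_ds(fa)):.2f}"
    )

# A liver-like mixture: mostly palmitic + linoleic + alpha-linolenic.
comp = chem.FattyAcidComposition.from_dict(
    {"16:0": 0.30, "18:1": 0.10, "18:2": 0.35, "18:3": 0.25}, total_lipid=120.0
)
profile = chem.composition_profile(comp)  # pooled group-count ratios
print(
    f"\ntissue composition: HCL={profile.hcl:.2f}, DS={profile.ds:.3f} "
    f"(pooled over all molecules; lies between the per-acid values)"
)
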