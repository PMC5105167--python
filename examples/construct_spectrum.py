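"""Construct a pseudo-native MS spectrum from site-specific PTM tables.

Builds an rhEPO-like glycoprotein model (three N-glycosylation sites, one
O-site, site abundances as would be quantified from middle-down XICs),
convolves the per-site modification distributions into the zero-charge
proteoform spectrum, and projects it through an 8+..10+ charge envelope
into a profile-mode m/z spectrum.
"""

from glycosim import construct_pseudo_native, rhepo_model, site_convolution

model = rhepo_model(seed=1)
print(f"model: {model.name}, backbone {model.backbone_mass:.2f} Da, "
      f"{model.n_sites} sites, {model.n_combinations} isoform combinations")

zc = site_convolution(model)
print(f"zero-charge spectrum: {len(zc)} resolved proteoform masses, "
      f"total probability {zc.abundances.sum():.6f}")
print(f"modal proteoform mass: {zc.modal_mass:.2f} Da "
      f"({zc.modal_mass - model.backbone_mass:.2f} Da of PTMs — "
      "the most likely total glycan load)")

profile = construct_pseudo_native(model)
lo, hi = profile.mz_range
print(f"profile spectrum: {len(profile)} points over m/z {lo:.0f}-{hi:.0f} Th "
      "(every proteoform appears once per charge state 8+, 9+, 10+)")
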