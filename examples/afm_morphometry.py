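"""Measure and classify single aggregates in a simulated AFM height map.

Renders monomer- and oligomer-scale spherical caps plus one protofilament,
images them through a 10 nm spherical tip (grey-scale dilation), adds a tilt
plane and 0.05 nm roughness, then runs the full morphometry pipeline:
flatten -> segment -> measure -> deconvolve -> classify.
"""

from aggresense import afm
from aggresense.simulate import AfmSimConfig, ParticleSpec, simulate_afm_map

specs = [
    ParticleSpec("spherical_cap", height_nm=0.4, diameter_nm=1.2, row_nm=60, col_nm=60),
    ParticleSpec("spherical_cap", height_nm=1.2, diameter_nm=4.0, row_nm=60, col_nm=180),
    ParticleSpec("spherical_cap", height_nm=2.5, diameter_nm=7.0, row_nm=60, col_nm=300),
    ParticleSpec("filament", height_nm=0.7, length_nm=300.0, width_nm=10.0,
                 row_nm=250, col_nm=200, theta=0.4),
]
cfg = AfmSimConfig(map_size=(400, 400), pixel_size_nm=1.0, particles=specs,
                   roughness_sd_nm=0.05, tilt=(0.5, 0.002, -0.001), seed=1)
hmap, truth, _ = simulate_afm_map(cfg)

particles = afm.analyze_height_map(hmap, afm.TipModel(tip_radius_nm=10.0))
print(particles[["max_height_nm", "fwhm_width_nm", "deconvolved_diameter_nm",
                 "length_nm", "aspect_ratio", "class"]].round(2).to_string())
print()
print("true classes:", ", ".join(truth.true_class))
# Heights survive tip convolution (angstrom accuracy); apparent widths are
# several-fold broadened by the 10 nm tip, and the deconvolution restores the
# true lateral scale. Classification follows height bands + elongation.
# Note: at 1 nm/px sampling the deconvolution of sub-tip-size monomers
# (d ~ 1 nm << R = 10 nm) hits its 0.1 nm floor; resolving those diameters
# needs finer sampling (see the morphometry docs), while heights and classes
# are unaffected.
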