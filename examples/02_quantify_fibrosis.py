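"""Quantify composition, heterogeneity, and patch geometry of one image.

Builds a fibrotic (IC-like) synthetic image and runs the three
quantification stages: composition fractions (V_e, V_f, V_mf and their sum
V_nm), the fibrosis measure (excess of V_nm over the donor-group mean of
22.09%), the 50-um tile heterogeneity profile, and connected-component
morphometry of fibrotic patches larger than 150 um^2.
"""

import warnings

from fibrocv import quantify, synthetic

spec = synthetic.SyntheticTissueSpec(
    group="IC", target_vnm=0.47, target_sigma_intra=27.0,
    pixel_size_nm=2000.0, rng_seed=3,
)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    image = synthetic.generate_tissue(spec)

fr = quantify.compute_fractions(image)
print(f"V_e  = {100 * fr.v_e:.2f}%   (extracellular space)")
print(f"V_f  = {100 * fr.v_f:.2f}%    (fibroblasts)")
print(f"V_mf = {100 * fr.v_mf:.2f}%    (myofibroblasts)")
print(f"V_nm = {100 * fr.v_nm:.2f}%   (non-myocyte fraction, the sum)")

fibrosis = quantify.compute_fibrosis(fr.v_nm, donor_mean_vnm=0.2209)
print(f"fibrosis = {100 * fibrosis:.2f}%  (V_nm excess over the donor mean)")

prof = quantify.heterogeneity_profile(image)
print(
    f"heterogeneity: {prof.n_tiles} tiles of 50 um, "
    f"mean V_nm = {100 * prof.mean_vnm:.2f}%, "
    f"sigma_intra = {prof.sigma_intra:.2f}%"
)

pf = quantify.patch_geometry(image.nonmyocyte_mask(), image.pixel_size_nm)
print(
    f"patches >150 um^2: n = {pf.n_patches}, "
    f"largest = {pf.largest_area_um2:,.0f} um^2, "
    f"mean major/minor axis = {pf.mean_major_axis_um:.1f}/"
    f"{pf.mean_minor_axis_um:.1f} um, axis ratio = {pf.mean_axis_ratio:.2f}"
)
print(
    "\nHigh sigma_intra and a large dominant patch are the image-level "
    "signatures of ischemic (replacement) fibrosis."
)
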