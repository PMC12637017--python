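# Default material set for vitrified biological specimens.
#
# fractions: elemental number fractions (sum to 1)
# density: g/cc
# avg_f0: tabulated composition-average elastic scattering factor at zero
#         angle (A); overrides the built-in parameterization when present
# mu: tabulated absorption coefficient (1/A) for the angular window
#     mu_window_mrad (used for multislice "absorption" beyond the aperture)
# elastic_mfp_nm / inelastic_mfp_nm: measured mean free paths at
#     inelastic_mfp_ref_keV (scaled as (lambda*gamma)^2 at other voltages)
materials:
  vitreous_ice:
    fractions: {O: 0.3333, H: 0.6667}
    density: 0.9
    avg_f0: 0.8885
    mu: 1.82e-4
    mu_window_mrad: [6.0, 3141.6]
    elastic_mfp_nm: 581.0
    inelastic_mfp_nm: 157.0
    inelastic_mfp_ref_keV: 200.0
  protein:
    fractions: {C: 0.31, N: 0.08, O: 0.08, H: 0.525, S: 0.005}
    density: 1.3
    avg_f0: 1.5170
    mu: 2.71e-4
    mu_window_mrad: [6.0, 3141.6]
    elastic_mfp_nm: 342.0
    inelastic_mfp_nm: 92.3
    inelastic_mfp_ref_keV: 200.0
  dna:
    fractions: {C: 0.24, N: 0.09, O: 0.14, H: 0.51, P: 0.02}
    density: 1.7
    avg_f0: 1.5808
    mu: 3.62e-4
    mu_window_mrad: [6.0, 3141.6]
    elastic_mfp_nm: 256.0
    inelastic_mfp_nm: 69.1
    inelastic_mfp_ref_keV: 200.0
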