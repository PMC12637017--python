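# cryocontrast

Contrast simulation for thick vitrified biological specimens. The package
models a T4-phage-like specimen (icosahedral protein capsid, genome as
concentric nucleic-acid cylinders, embedded in a vitreous-ice slab) and
simulates how it images under:

- **Zero-loss energy-filtered TEM** — multislice phase-contrast with complex
  (absorptive) phase gratings, CTF with temporal/spatial coherence envelopes,
  inelastic dose budgeting and Poisson shot noise.
- **Tilt-corrected bright-field STEM (tcBF)** — probe scanning with 4D
  recording on a segmented annular detector, per-bin parallax correction
  `(Cs·ω² − Δf)·ω` and bright-field summation; equivalent to TEM by
  reciprocity but with no energy-filter fluence loss.
- **Incoherent (amplitude) STEM** — a lightweight Monte Carlo of elastic
  (screened-Rutherford) + inelastic (Lorentzian dipole) electron
  trajectories, binned onto annular detectors.
- **Low-loss EELS** — log-ratio thickness estimation, energy-window
  statistics, and synthetic thick-specimen spectra via Poisson multiple
  plasmon scattering.

## Layout

| module | contents |
| --- | --- |
| `cryocontrast.physics` | relativistic beam quantities, materials, scattering factors, phase/absorption per thickness, attenuation |
| `cryocontrast.geometry` | CSG phage model, embedding in ice, voxelization |
| `cryocontrast.multislice` | phase gratings, Fresnel propagation, exit waves, slice-thickness error budget |
| `cryocontrast.optics` | aberration function, CTF, coherence envelopes, Scherzer defocus, depth of field, resolution conversions |
| `cryocontrast.tem` | exit wave → aberrated image → fluence budget → counts |
| `cryocontrast.stem` | probe formation, 4D recording, parallax correction, tcBF summation |
| `cryocontrast.eels` | spectrum synthesis/analysis, MSA & two-column I/O |
| `cryocontrast.mc` | Monte Carlo trajectory simulation and per-bin images |
| `cryocontrast.cli` / `cryocontrast.io` | YAML-driven CLI, MRC/TIFF/HDF5/CSV/JSON writers |

Default material constants (compositions, densities, tabulated scattering
factors, absorption coefficients and mean free paths) ship in
`cryocontrast/data/materials.yaml` and can be overridden by a user file.

## CLI

One YAML config drives all modes (`tem`, `tcbf-stem`, `mc-stem`, `eels`):

```sh
cryocontrast run config.yaml --out outdir
cryocontrast ctf --defocus-nm 500 --focal-spread-nm 50 --out ctf.csv
cryocontrast make-fixtures fixtures/ --seed 0
```

Exit codes: 0 success, 2 configuration error, 3 numerical failure. Every run
writes a `summary.json` with a config digest, seed and derived quantities
(Scherzer defocus, depth of field, zero-loss fraction, count statistics).

Example TEM config:

```yaml
mode: tem
seed: 1
beam: {energy_keV: 200.0}
optics: {cs_mm: 2.0, defocus_nm: 500.0, aperture_mrad: 4.0}
specimen: {ice_thickness_nm: 200.0, orientation: top}
raster: {N: 512, L_nm: 128.0, delta_t_nm: 2.0}
fluence: 4.0
```

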