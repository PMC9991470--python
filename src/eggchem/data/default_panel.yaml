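# 16-element eggshell analysis panel: emission wavelength (nm) and
# detection limit (ug/g, 3-sigma of 11 blank replicates) per element,
# plus class-conditional concentration summaries (mean/SD, ug/g) for
# the two husbandry classes used by the synthetic profile generator.
elements:
  - {symbol: Zn, wavelength_nm: 213.85, detection_limit: 0.05}
  - {symbol: Pb, wavelength_nm: 220.35, detection_limit: 0.09}
  - {symbol: Cd, wavelength_nm: 226.50, detection_limit: 0.03}
  - {symbol: Co, wavelength_nm: 228.61, detection_limit: 0.03}
  - {symbol: Ni, wavelength_nm: 231.60, detection_limit: 0.05}
  - {symbol: Fe, wavelength_nm: 238.20, detection_limit: 0.04}
  - {symbol: Mn, wavelength_nm: 257.61, detection_limit: 0.07}
  - {symbol: Cr, wavelength_nm: 267.71, detection_limit: 0.02}
  - {symbol: Mg, wavelength_nm: 280.26, detection_limit: 0.08}
  - {symbol: Cu, wavelength_nm: 324.75, detection_limit: 0.07}
  - {symbol: Se, wavelength_nm: 361.38, detection_limit: 0.04}
  - {symbol: Ca, wavelength_nm: 393.36, detection_limit: 0.08}
  - {symbol: Al, wavelength_nm: 396.15, detection_limit: 0.10}
  - {symbol: Sr, wavelength_nm: 407.77, detection_limit: 0.02}
  - {symbol: Na, wavelength_nm: 589.60, detection_limit: 0.33}
  - {symbol: K, wavelength_nm: 766.49, detection_limit: 0.76}

producing_areas: [Guizhou, Henan, Anhui, Jiangsu, Hubei, Guangxi, Hunan]

class_distributions:
  free-range:
    Zn: {mean: 1.72, sd: 0.39}
    Pb: {mean: 1.04, sd: 0.27}
    Cd: {nondetect: true}
    Co: {mean: 0.22, sd: 0.04}
    Ni: {mean: 0.44, sd: 0.12}
    Fe: {mean: 2.1, sd: 0.6}
    Mn: {mean: 0.67, sd: 0.13}
    Cr: {mean: 0.71, sd: 0.28}
    Mg: {mean: 6042, sd: 2106}
    Cu: {mean: 1.56, sd: 0.31}
    Se: {mean: 4.22, sd: 1.68}
    Ca: {mean: 366310, sd: 46778}
    Al: {mean: 71.9, sd: 6.5}
    Sr: {mean: 120.4, sd: 24.8}
    Na: {mean: 2156, sd: 388}
    K: {mean: 1850, sd: 302}
  caged:
    Zn: {mean: 2.33, sd: 0.51}
    Pb: {mean: 2.16, sd: 0.19}
    Cd: {mean: 0.34, sd: 0.08}
    Co: {mean: 0.32, sd: 0.09}
    Ni: {mean: 0.59, sd: 0.10}
    Fe: {mean: 3.2, sd: 1.0}
    Mn: {mean: 1.01, sd: 0.31}
    Cr: {mean: 2.32, sd: 1.03}
    Mg: {mean: 5363, sd: 1849}
    Cu: {mean: 2.13, sd: 0.55}
    Se: {mean: 2.18, sd: 1.01}
    Ca: {mean: 342560, sd: 35458}
    Al: {mean: 88.5, sd: 11.7}
    Sr: {mean: 171.3, sd: 44.6}
    Na: {mean: 3016, sd: 612}
    K: {mean: 2305, sd: 226}
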