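# SRM quantification configuration for the four marker phenols of
# Polygonum multiflorum: gallic acid (GA), emodin (EM),
# trans-2,3,5,4'-tetrahydroxystilbene-2-O-b-D-glucopyranoside (THSG) and
# emodin-8-O-b-D-glucopyranoside (EMG).

transitions:
  GA:   {precursor_mz: 169.0, product_mz: 125.0, collision_energy: 35, isolation_width: 1.0}
  EM:   {precursor_mz: 269.0, product_mz: 225.0, collision_energy: 35, isolation_width: 1.0}
  THSG: {precursor_mz: 405.0, product_mz: 243.0, collision_energy: 35, isolation_width: 1.0}
  EMG:  {precursor_mz: 431.0, product_mz: 269.0, collision_energy: 35, isolation_width: 1.0}

# Mixed working-standard stocks (ug/mL); the calibration series dilutes
# these by the factors below.
stock_concentrations:
  GA: 8.0
  EM: 2.75
  THSG: 210.0
  EMG: 228.0

dilution_factors: [0.5, 0.25, 0.125, 0.0625, 0.03125, 0.015625, 0.0078125]

# Published calibration lines (area = slope * conc + intercept, conc in
# ug/mL) with their reported test ranges, r^2 and LOD/LOQ (ng/mL). The
# printed lower range bounds are kept verbatim even where they disagree
# with stock/128.
calibration_reference:
  GA:   {slope: 3598.5, intercept: 205.82,  r2: 0.9997, range: [0.03, 4.00],   lod_ng_ml: 0.03, loq_ng_ml: 0.10}
  EM:   {slope: 25639,  intercept: 2283.1,  r2: 0.9916, range: [0.01, 1.40],   lod_ng_ml: 0.01, loq_ng_ml: 0.02}
  THSG: {slope: 652.2,  intercept: -5013.2, r2: 0.9997, range: [1.15, 105.00], lod_ng_ml: 0.01, loq_ng_ml: 0.02}
  EMG:  {slope: 7690.7, intercept: 14652,   r2: 0.9998, range: [0.29, 114.00], lod_ng_ml: 0.01, loq_ng_ml: 0.06}

# Sample preparation: powdered dried root extracted under reflux in methanol.
extract_volume_ml: 25.0
sample_mass_g: 0.2

# UHPLC gradient recorded for reference (acetonitrile % over minutes on a
# BEH C18 2.1 x 50 mm, 1.7 um column; 0.1% formic acid in water; 400 uL/min;
# negative ESI, scan m/z 150-1200).
gradient:
  - [0.0, 13]
  - [3.5, 35]
  - [7.5, 90]
  - [8.5, 95]
  - [10.0, 95]
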