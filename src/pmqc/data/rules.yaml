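# Diagnostic-ion rule base for phenolic constituents of Polygonum multiflorum.
#
# Evidence model: an exact-tier diagnostic match (both values high-resolution,
# +-0.01 Da) scores 2; a nominal-tier match scores 2 when the matching peak is
# a base peak (rel. intensity 100) and 1 when its relative intensity is at
# least min_relint (default 25); each matched supporting neutral-loss name
# scores 1. A rule fires when at least one diagnostic ion matched and the
# total reaches required_score. Precursor ions count as high-resolution
# candidates.
#
# The stilbene, emodin-type, physcion-type and galloyl rules carry the
# literature diagnostic ions for these families; rules marked
# "fixture-derived" are transcribed from the shipped 25-compound library's
# fragment columns.

family_priority: [stilbene, anthraquinone, tannin, naphthalene, sugar]

rules:
  - name: stilbene-core
    family: stilbene
    diagnostic_mzs: [405.1177, 243.0661]   # tetrahydroxystilbene glucoside / aglycone
    supporting_losses: [hexosyl, galloyl, caffeoyl, coumaroyl]
    required_score: 2

  - name: emodin-anthraquinone
    family: anthraquinone
    diagnostic_mzs: [269.0447, 225.0544, 241.0492]
    supporting_losses: [hexosyl, malonyl, CO2]
    required_score: 2

  - name: physcion-anthraquinone
    family: anthraquinone
    diagnostic_mzs: [240, 268]             # odd-electron radical fragments
    supporting_losses: [methyl_radical]
    odd_electron: true
    required_score: 2

  - name: citreorosein-anthraquinone   # fixture-derived
    family: anthraquinone
    diagnostic_mzs: [285, 303]
    supporting_losses: [hexosyl]
    required_score: 2

  - name: galloyl-tannin
    family: tannin
    diagnostic_mzs: [169.0136, 125.0244]
    supporting_losses: []
    required_score: 2

  - name: flavanol-procyanidin         # fixture-derived
    family: tannin
    diagnostic_mzs: [289.0708, 425, 407]
    supporting_losses: []
    required_score: 2

  - name: naphthalene-glycoside        # fixture-derived
    family: naphthalene
    diagnostic_mzs: [245, 259]
    supporting_losses: [methyl_radical, hexosyl]
    required_score: 2
    require_loss: true

  - name: sugar                        # fixture-derived
    family: sugar
    diagnostic_mzs: [179.0556, 161, 143, 113, 89]
    supporting_losses: []
    required_score: 2
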