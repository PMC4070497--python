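components:
- name: nadph_free
  center_nm: 463.0
  fwhm_nm: 115.0
  asymmetry: 0.0
  amplitude: 1.0
  center_free: false
  fwhm_free: false
  asymmetry_free: false
- name: nadph_bound
  center_nm: 444.0
  fwhm_nm: 105.0
  asymmetry: 0.0
  amplitude: 1.0
  center_free: false
  fwhm_free: false
  asymmetry_free: false
- name: flavins
  center_nm: 526.0
  fwhm_nm: 81.0
  asymmetry: 0.0
  amplitude: 1.0
  center_free: false
  fwhm_free: false
  asymmetry_free: false
- name: vitamin_a
  center_nm: 488.0
  fwhm_nm: 102.0
  asymmetry: 0.0
  amplitude: 1.0
  center_free: false
  fwhm_free: false
  asymmetry_free: false
- name: fatty_acids
  center_nm: 470.0
  fwhm_nm: 90.0
  asymmetry: 0.0
  amplitude: 1.0
  center_free: false
  fwhm_free: false
  asymmetry_free: false
- name: proteins
  center_nm: 415.0
  fwhm_nm: 100.0
  asymmetry: 0.0
  amplitude: 1.0
  center_free: true
  fwhm_free: true
  asymmetry_free: true
  bounds:
    center_nm:
    - 380.0
    - 440.0
    fwhm_nm:
    - 60.0
    - 140.0
    asymmetry:
    - -1.0
    - 1.0
- name: lipopigments
  center_nm: 587.0
  fwhm_nm: 80.0
  asymmetry: 0.0
  amplitude: 1.0
  center_free: true
  fwhm_free: true
  asymmetry_free: true
  bounds:
    center_nm:
    - 560.0
    - 620.0
    fwhm_nm:
    - 50.0
    - 110.0
    asymmetry:
    - -1.0
    - 1.0
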