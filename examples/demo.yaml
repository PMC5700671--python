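# End-to-end demo: simulate a synthetic hospital population and run the
# whole analysis (cohort extraction, descriptive tables, phenome-wide
# screens, adjusted mortality models).
#
#   dysnat run-all --config examples/demo.yaml --out demo_out
#
# Omitted generator fields keep their defaults: admission sodium
# 138.3 +/- 3.9 mmol/L per stay, ~4% cohort mortality, sodium-category
# mortality effects at the published adjusted odds ratios, and a 60-code
# panel with the 13 published dual-associated codes planted at their
# published odds ratios.
simulate:
  n_patients: 20000
seed: 7
alpha_family: 0.05
out_dir: demo_out
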