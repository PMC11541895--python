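# Simulation spec for `ccmeldi simulate --spec sim_spec.yaml --out run.mzML`
#
# panel: sum-composition species -> list of C=C isomers.  Per isomer:
#   position  Δ locant (carboxyl carbon = C1)
#   geometry  Z or E (E elutes later by trans_offset)
#   fraction  molar fraction; must sum to 1 per species
#   response_factor  optional per-isomer response (default 1.0)
#   label     optional isotope tag, e.g. "13C1@1-9" (positions retained
#             on the carboxylate side shift the diagnostic pair)
#
# Remaining keys override SimSpec defaults (units in comments).
panel:
  "FA 18:1":
    - {position: 9,  geometry: Z, fraction: 0.50}
    - {position: 9,  geometry: E, fraction: 0.20}
    - {position: 10, geometry: E, fraction: 0.10}
    - {position: 11, geometry: Z, fraction: 0.20}
  "FA 16:1":
    - {position: 9,  geometry: Z, fraction: 0.70}
    - {position: 11, geometry: E, fraction: 0.30}

rt_slope: -0.30        # min per Δ unit (retention falls as Δ grows)
rt_intercept: 18.0     # min
trans_offset: 0.6      # min; E after Z
sigma_s: 3.0           # chromatographic peak σ, seconds
rt_start: 12.0         # min, simulated window
rt_end: 19.0
noise_cv: 0.01         # log-normal sd on peak amplitude
rt_jitter_min: 0.01    # apex jitter, min
seed: 42
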