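# Built-in simulation protocols.  normal_dc and caikk_dc differ only in the
# IKKb degradation rate (0.840 vs 0.216 1/h); the caIKK electroporation is
# modeled solely through that slowed degradation.  The in-vitro T-cell priming
# protocol adds a fresh DC batch at t = 0, 168 and 336 h (weekly stimulations).
normal_dc:
  stimulus: [[0, 1]]
caikk_dc:
  stimulus: [[0, 1]]
  overrides:
    k_deg_IKKb: 0.216
lps:
  stimulus: [[0, 1]]
tcell_invitro_normal:
  stimulus: [[0, 1]]
  restimulation: [0, 168, 336]
tcell_invitro_caikk:
  stimulus: [[0, 1]]
  overrides:
    k_deg_IKKb: 0.216
  restimulation: [0, 168, 336]
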