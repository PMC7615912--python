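{
 "_provenance": "synthetic geometric construction at realistic 80S length scales; not derived from deposited atomic models",
 "mrna_entry": [
  50.0,
  -85.0,
  -50.0
 ],
 "mrna_exit": [
  -45.0,
  -85.0,
  -50.0
 ],
 "p_stalk": [
  30.0,
  70.0,
  35.0
 ],
 "gcn1_anchor": [
  -64.748775,
  -68.049428,
  46.633632
 ]
}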