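{
 "_provenance": "synthetic geometric construction at realistic 80S length scales; not derived from deposited atomic models",
 "GCN1": {
  "anchor": "leading ribosome of the disome",
  "spheres": [
   {
    "center": [
     -201.529414,
     -139.493524,
     84.953802
    ],
    "radius": 20.0
   },
   {
    "center": [
     -64.748775,
     -68.049428,
     46.633632
    ],
    "radius": 20.0
   }
  ]
 }
}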