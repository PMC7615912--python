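{
 "_provenance": "synthetic geometric construction at realistic 80S length scales; not derived from deposited atomic models",
 "ribosome_80s": {
  "spheres": [
   {
    "name": "60S",
    "center": [
     55.0,
     0.0,
     0.0
    ],
    "radius": 80.0
   },
   {
    "name": "40S",
    "center": [
     -60.0,
     0.0,
     0.0
    ],
    "radius": 55.0
   }
  ]
 },
 "ribosome_80s_pstalk": {
  "spheres": [
   {
    "name": "60S",
    "center": [
     55.0,
     0.0,
     0.0
    ],
    "radius": 80.0
   },
   {
    "name": "40S",
    "center": [
     -60.0,
     0.0,
     0.0
    ],
    "radius": 55.0
   },
   {
    "name": "P_stalk",
    "center": [
     30.0,
     70.0,
     35.0
    ],
    "radius": 25.0
   }
  ]
 }
}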