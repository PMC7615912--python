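{
 "_provenance": "synthetic geometric construction at realistic 80S length scales; not derived from deposited atomic models",
 "collided": {
  "t": [
   -174.51664743005085,
   -140.22211491663342,
   0.0
  ],
  "Rrel": [
   [
    0.25881904510252074,
    -0.9659258262890683,
    0.0
   ],
   [
    0.9659258262890683,
    0.25881904510252074,
    0.0
   ],
   [
    0.0,
    0.0,
    1.0
   ]
  ],
  "tau_t": 15.0,
  "tau_r": 25.0
 },
 "helical": {
  "t": [
   -125.31876220041546,
   -158.37346745954173,
   42.0
  ],
  "Rrel": [
   [
    -0.08715574274765824,
    -0.9961946980917455,
    0.0
   ],
   [
    0.9961946980917455,
    -0.08715574274765824,
    0.0
   ],
   [
    0.0,
    0.0,
    1.0
   ]
  ],
  "tau_t": 15.0,
  "tau_r": 25.0
 }
}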