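{
 "parameters": [
  {
   "kind": "input_scale",
   "ref": null,
   "name": "alpha_r0",
   "lower": 0.5,
   "upper": 1.5
  },
  {
   "kind": "alpha",
   "ref": "r1",
   "name": "alpha_r1",
   "lower": 5.0,
   "upper": 15.0
  },
  {
   "kind": "alpha",
   "ref": "r2",
   "name": "alpha_r2",
   "lower": 5.0,
   "upper": 15.0
  },
  {
   "kind": "alpha",
   "ref": "r3",
   "name": "alpha_r3",
   "lower": 5.0,
   "upper": 15.0
  },
  {
   "kind": "alpha",
   "ref": "r4",
   "name": "alpha_r4",
   "lower": 1.5,
   "upper": 4.5
  },
  {
   "kind": "alpha",
   "ref": "r5",
   "name": "alpha_r5",
   "lower": 0.05,
   "upper": 0.15000000000000002
  },
  {
   "kind": "kinetic_order",
   "ref": [
    "X4",
    "r1"
   ],
   "name": "g_X4_r1",
   "lower": -2.0,
   "upper": 0.0
  }
 ],
 "objective": {
  "species": "X4",
  "tspan": [
   0,
   20
  ],
  "t_upper": 20
 }
}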