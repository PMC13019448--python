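{
 "baseline": [
  1.0,
  0,
  0,
  0,
  0
 ],
 "pulses": [
  [
   [
    5.0,
    15.0,
    10.0
   ],
   [
    25.0,
    35.0,
    5.0
   ]
  ],
  [],
  [],
  [],
  []
 ]
}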