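{
 "reference": [
  "R1",
  "R2",
  "R3"
 ],
 "include_product_in_desired": true,
 "objectives": [
  {
   "name": "product",
   "numerator": "R4",
   "role": "product_min_yield"
  }
 ]
}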