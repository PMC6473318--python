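{
 "version": "1.0.0",
 "checksum": "78a29f38d1f6322a336279aa55948ab84b9b1266b5340fefb4c01469deedf942",
 "category_aliases": {
  "attention_deficit_hyperactivity_disorder": [
   "attention deficit disorder with hyperactivity"
  ]
 }
}
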