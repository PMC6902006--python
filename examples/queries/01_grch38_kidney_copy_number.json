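{
 "gcm": {
  "assembly": [
   "grch38"
  ],
  "data_type": [
   "copy number segment",
   "masked copy number segment"
  ],
  "tissue": [
   "kidney"
  ]
 },
 "type": "original",
 "kv": {}
}
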