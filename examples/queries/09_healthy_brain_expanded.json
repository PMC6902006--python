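{
 "gcm": {
  "assembly": [
   "hg19"
  ],
  "is_healthy": [
   "true"
  ],
  "tissue": [
   "brain"
  ],
  "gender": [
   "male"
  ]
 },
 "type": "expanded",
 "kv": {}
}
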