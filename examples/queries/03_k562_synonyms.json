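{
 "gcm": {
  "cell": [
   "k562"
  ]
 },
 "type": "synonym",
 "kv": {}
}
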