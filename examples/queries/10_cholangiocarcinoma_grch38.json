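{
 "gcm": {
  "source": [
   "tcga"
  ],
  "assembly": [
   "grch38"
  ],
  "disease": [
   "cholangiocarcinoma"
  ]
 },
 "type": "original",
 "kv": {}
}
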