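{
 "gcm": {
  "source": [
   "encode"
  ],
  "technique": [
   "chip-seq"
  ],
  "file_format": [
   "narrowpeak"
  ],
  "cell": [
   "h1 cells"
  ]
 },
 "type": "synonym",
 "kv": {}
}
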