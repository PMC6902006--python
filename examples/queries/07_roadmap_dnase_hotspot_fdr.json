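{
 "gcm": {
  "source": [
   "roadmap epigenomics"
  ],
  "technique": [
   "dnase-seq"
  ],
  "pipeline": [
   "hotspot"
  ],
  "cell": [
   "h1 cells"
  ]
 },
 "type": "synonym",
 "kv": {
  "fdr_0": {
   "type_query": "key",
   "exact": false,
   "query": {
    "gcm": {},
    "pairs": {
     "manually_curated__fdr_threshold": [
      "0.01"
     ]
    }
   }
  }
 }
}
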