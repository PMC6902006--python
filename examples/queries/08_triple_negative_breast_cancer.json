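{
 "gcm": {
  "project_name": [
   "tcga-brca"
  ],
  "tissue": [
   "breast"
  ]
 },
 "type": "original",
 "kv": {
  "er": {
   "type_query": "key",
   "exact": true,
   "query": {
    "gcm": {},
    "pairs": {
     "clinical__brca_shared__breast_carcinoma_estrogen_receptor_status": [
      "negative"
     ]
    }
   }
  },
  "pr": {
   "type_query": "key",
   "exact": true,
   "query": {
    "gcm": {},
    "pairs": {
     "clinical__brca_shared__breast_carcinoma_progesterone_receptor_status": [
      "negative"
     ]
    }
   }
  },
  "her2": {
   "type_query": "key",
   "exact": true,
   "query": {
    "gcm": {},
    "pairs": {
     "clinical__brca_shared__lab_proc_her2_neu_immunohistochemistry_receptor_status": [
      "negative"
     ]
    }
   }
  }
 }
}
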