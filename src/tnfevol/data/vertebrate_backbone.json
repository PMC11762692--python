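{
 "version": "1",
 "initial_state": {
  "lineage_label": "metazoan_ancestor",
  "chromosomes": [
   {
    "name": "chrA",
    "genes": [
     {
      "id": "V1",
      "origin": "V1"
     }
    ]
   }
  ]
 },
 "events": [
  {
   "branch": "early_metazoan",
   "type": "TANDEM_DUP",
   "target": "V1",
   "new_id": "V2",
   "new_origin": "V2"
  },
  {
   "branch": "pre_vertebrate",
   "type": "DUP_TRANSPOSITION",
   "target": "V1",
   "destination": "chrB",
   "new_id": "V12",
   "new_origin": "V12",
   "relabel_target_id": "V11",
   "relabel_target_origin": "V11"
  },
  {
   "branch": "pre_vertebrate",
   "type": "DUP_TRANSPOSITION",
   "target": "V2",
   "destination": "chrB",
   "new_id": "V22",
   "new_origin": "V22",
   "relabel_target_id": "V21",
   "relabel_target_origin": "V21"
  },
  {
   "branch": "vertebrate_ancestor",
   "type": "WGD",
   "origin_suffixes": [
    "1",
    "2"
   ],
   "id_map": {
    "V11": [
     "V111",
     "V112"
    ],
    "V21": [
     "V211",
     "V212"
    ],
    "V12": [
     "V121",
     "V122"
    ],
    "V22": [
     "V221",
     "V222"
    ]
   }
  }
 ]
}
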