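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
  },
  {
   "branch": "cyclostome_ancestor",
   "type": "LOSS",
   "target": "V211"
  },
  {
   "branch": "cyclostome_ancestor",
   "type": "LOSS",
   "target": "V112"
  },
  {
   "branch": "cyclostome_ancestor",
   "type": "LOSS",
   "target": "V122"
  },
  {
   "branch": "cyclostome_ancestor",
   "type": "TANDEM_DUP",
   "target": "V111",
   "new_id": "TNFSF-C2"
  },
  {
   "branch": "Petromyzon_marinus",
   "type": "TRIPLICATION",
   "id_map": {
    "V111": [
     "TNFSF-C1",
     "C1-t2",
     "C1-t3"
    ],
    "TNFSF-C2": [
     "TNFSF-C2",
     "C2-t2",
     "C2-t3"
    ],
    "V121": [
     "TNFSF-C3",
     "C3-t2",
     "C3-t3"
    ],
    "V212": [
     "TNFSF-C4",
     "TNFSF-C4c",
     "C4-t3"
    ],
    "V221": [
     "TNFSF-C5",
     "C5-t2",
     "C5-t3"
    ],
    "V222": [
     "TNFSF-C6",
     "C6-t2",
     "C6-t3"
    ]
   }
  },
  {
   "branch": "Petromyzon_marinus",
   "type": "LOSS",
   "target": "C1-t2"
  },
  {
   "branch": "Petromyzon_marinus",
   "type": "LOSS",
   "target": "C1-t3"
  },
  {
   "branch": "Petromyzon_marinus",
   "type": "LOSS",
   "target": "C2-t2"
  },
  {
   "branch": "Petromyzon_marinus",
   "type": "LOSS",
   "target": "C2-t3"
  },
  {
   "branch": "Petromyzon_marinus",
   "type": "LOSS",
   "target": "C3-t2"
  },
  {
   "branch": "Petromyzon_marinus",
   "type": "LOSS",
   "target": "C3-t3"
  },
  {
   "branch": "Petromyzon_marinus",
   "type": "LOSS",
   "target": "C4-t3"
  },
  {
   "branch": "Petromyzon_marinus",
   "type": "LOSS",
   "target": "C5-t2"
  },
  {
   "branch": "Petromyzon_marinus",
   "type": "LOSS",
   "target": "C5-t3"
  },
  {
   "branch": "Petromyzon_marinus",
   "type": "LOSS",
   "target": "C6-t2"
  },
  {
   "branch": "Petromyzon_marinus",
   "type": "LOSS",
   "target": "C6-t3"
  },
  {
   "branch": "Petromyzon_marinus",
   "type": "TANDEM_DUP",
   "target": "TNFSF-C4",
   "new_id": "TNFSF-C4b"
  },
  {
   "branch": "Petromyzon_marinus",
   "type": "TANDEM_DUP",
   "target": "TNFSF-C5",
   "new_id": "TNFSF-C5b"
  }
 ]
}
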