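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
   "branch": "gnathostome_post_wgd2",
   "type": "WGD",
   "origin_suffixes": [
    "1",
    "2"
   ],
   "id_map": {
    "V111": [
     "TNFSF15",
     "TNFSF1/2"
    ],
    "V211": [
     "TNFSF-F5",
     "V21-chr6"
    ],
    "V112": [
     "TNFSF6",
     "TNFSF14"
    ],
    "V212": [
     "TNFSF4",
     "TNFSF9"
    ],
    "V121": [
     "TNFSF12",
     "TNFSF10"
    ],
    "V221": [
     "TNFSF13",
     "V22-chr3"
    ],
    "V122": [
     "TNFSF5",
     "TNFSF11"
    ],
    "V222": [
     "EDA",
     "TNFSF13B"
    ]
   }
  },
  {
   "branch": "gnathostome_ancestor",
   "type": "LOSS",
   "target": "V21-chr6"
  },
  {
   "branch": "gnathostome_ancestor",
   "type": "LOSS",
   "target": "V22-chr3"
  },
  {
   "branch": "gnathostome_ancestor",
   "type": "TANDEM_DUP",
   "target": "TNFSF1/2",
   "new_id": "TNFSF3"
  },
  {
   "branch": "gnathostome_ancestor",
   "type": "TANDEM_DUP",
   "target": "TNFSF1/2",
   "new_id": "TNFSF-F2"
  },
  {
   "branch": "gnathostome_ancestor",
   "type": "TANDEM_DUP",
   "target": "TNFSF15",
   "new_id": "TNFSF-F1"
  },
  {
   "branch": "gnathostome_ancestor",
   "type": "TANDEM_DUP",
   "target": "TNFSF-F1",
   "new_id": "TNFSF-F6"
  },
  {
   "branch": "gnathostome_ancestor",
   "type": "TANDEM_DUP",
   "target": "TNFSF11",
   "new_id": "TNFSF11B"
  },
  {
   "branch": "gnathostome_ancestor",
   "type": "TANDEM_DUP",
   "target": "TNFSF10",
   "new_id": "TNFSF-F3"
  },
  {
   "branch": "gnathostome_ancestor",
   "type": "TANDEM_DUP",
   "target": "EDA",
   "new_id": "BALM"
  },
  {
   "branch": "Homo_sapiens",
   "type": "LOSS",
   "target": "TNFSF-F1"
  },
  {
   "branch": "Homo_sapiens",
   "type": "LOSS",
   "target": "TNFSF-F2"
  },
  {
   "branch": "Homo_sapiens",
   "type": "LOSS",
   "target": "TNFSF-F3"
  },
  {
   "branch": "Homo_sapiens",
   "type": "LOSS",
   "target": "TNFSF-F5"
  },
  {
   "branch": "Homo_sapiens",
   "type": "LOSS",
   "target": "TNFSF-F6"
  },
  {
   "branch": "Homo_sapiens",
   "type": "LOSS",
   "target": "BALM"
  },
  {
   "branch": "Homo_sapiens",
   "type": "LOSS",
   "target": "TNFSF11B"
  },
  {
   "branch": "Homo_sapiens",
   "type": "TANDEM_DUP",
   "target": "TNFSF1/2",
   "new_id": "TNFSF1",
   "relabel_target_id": "TNFSF2"
  },
  {
   "branch": "Homo_sapiens",
   "type": "TANDEM_DUP",
   "target": "TNFSF9",
   "new_id": "TNFSF7"
  },
  {
   "branch": "Homo_sapiens",
   "type": "DUP_TRANSPOSITION",
   "target": "TNFSF7",
   "new_id": "TNFSF8",
   "destination": "chrA"
  },
  {
   "branch": "Homo_sapiens",
   "type": "TANDEM_DUP",
   "target": "TNFSF4",
   "new_id": "TNFSF18"
  }
 ]
}
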