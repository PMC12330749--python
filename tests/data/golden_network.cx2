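[
 {
  "CXVersion": "2.0",
  "hasFragments": false
 },
 {
  "attributeDeclarations": [
   {
    "edges": {
     "bel": {
      "d": "string"
     },
     "evidence": {
      "d": "list_of_string"
     },
     "interaction": {
      "d": "string"
     },
     "source": {
      "d": "list_of_string"
     }
    },
    "networkAttributes": {
     "generator": {
      "d": "string"
     },
     "name": {
      "d": "string"
     },
     "sources": {
      "d": "list_of_string"
     }
    },
    "nodes": {
     "bel": {
      "d": "string"
     },
     "identifier": {
      "d": "string"
     },
     "name": {
      "d": "string"
     },
     "namespace": {
      "d": "string"
     }
    }
   }
  ]
 },
 {
  "networkAttributes": [
   {
    "generator": "beltograph",
    "name": "golden",
    "sources": [
     "PMCgolden"
    ]
   }
  ]
 },
 {
  "nodes": [
   {
    "id": 0,
    "v": {
     "bel": "p(HGNC:TP53)",
     "identifier": "TP53",
     "name": "TP53",
     "namespace": "HGNC"
    }
   },
   {
    "id": 1,
    "v": {
     "bel": "p(HGNC:MDM2)",
     "identifier": "MDM2",
     "name": "MDM2",
     "namespace": "HGNC"
    }
   }
  ]
 },
 {
  "edges": [
   {
    "id": 0,
    "s": 0,
    "t": 1,
    "v": {
     "bel": "p(HGNC:TP53) increases p(HGNC:MDM2)",
     "evidence": [
      "PMCgolden|0|TP53 increases MDM2 expression."
     ],
     "interaction": "increases",
     "source": [
      "PMCgolden"
     ]
    }
   }
  ]
 },
 {
  "status": [
   {
    "error": "",
    "success": true
   }
  ]
 }
]
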