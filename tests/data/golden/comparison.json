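{
 "delta_assortativity": {
  "degree": {
   "pearson": {
    "layers": [
     "conformation",
     "interaction",
     "similarity"
    ],
    "values": [
     [
      0.0,
      -0.0739527897294761,
      0.06261899243783685
     ],
     [
      -0.0739527897294761,
      0.0,
      0.04494841058068845
     ],
     [
      0.06261899243783685,
      0.04494841058068845,
      0.0
     ]
    ]
   },
   "spearman": {
    "layers": [
     "conformation",
     "interaction",
     "similarity"
    ],
    "values": [
     [
      0.0,
      -0.4337634276776777,
      0.04232648799567926
     ],
     [
      -0.4337634276776777,
      0.0,
      0.03293861108176785
     ],
     [
      0.04232648799567926,
      0.03293861108176785,
      0.0
     ]
    ]
   }
  },
  "strength": {
   "pearson": {
    "layers": [
     "conformation",
     "interaction",
     "similarity"
    ],
    "values": [
     [
      0.0,
      -0.0742938089198785,
      0.06278880202525114
     ],
     [
      -0.0742938089198785,
      0.0,
      0.04135620233888805
     ],
     [
      0.06278880202525114,
      0.04135620233888805,
      0.0
     ]
    ]
   },
   "spearman": {
    "layers": [
     "conformation",
     "interaction",
     "similarity"
    ],
    "values": [
     [
      0.0,
      -0.4897499630668073,
      -0.06344701549518492
     ],
     [
      -0.4897499630668073,
      0.0,
      0.013811492348221543
     ],
     [
      -0.06344701549518492,
      0.013811492348221543,
      0.0
     ]
    ]
   }
  }
 },
 "delta_degree": {
  "ESR1": 20,
  "G0001": 16,
  "G0002": 17,
  "G0003": 19,
  "G0004": 12,
  "G0005": 9,
  "G0006": 11,
  "G0007": 9,
  "G0008": 18,
  "G0009": 8,
  "G0010": 7,
  "G0011": 11,
  "G0012": 14,
  "G0013": 10,
  "G0014": 10,
  "G0015": 10,
  "G0016": 18,
  "G0017": 5,
  "G0018": 18,
  "G0019": 1,
  "G0020": 4,
  "G0021": 9,
  "G0022": 19,
  "G0023": 4,
  "G0024": 22,
  "G0025": 14,
  "G0026": 11,
  "G0027": 10,
  "G0028": 9,
  "G0029": 25,
  "G0030": 16,
  "G0031": 12,
  "G0032": 14,
  "G0033": 18,
  "G0034": 24,
  "G0035": 25,
  "G0036": 15,
  "G0037": 9,
  "G0038": 21,
  "G0039": 13,
  "G0040": 15,
  "G0041": 7,
  "G0042": 16,
  "G0043": 16,
  "G0044": 21
 },
 "delta_gene_count": 15,
 "delta_mutation_counts": {
  "driver": 356,
  "passenger": 144,
  "unclassified": 0
 },
 "delta_strength": {
  "ESR1": 19.5420745597522,
  "G0001": 15.486461224274997,
  "G0002": 16.578031356325,
  "G0003": 18.591056504991098,
  "G0004": 11.737246655469495,
  "G0005": 8.735155908759,
  "G0006": 10.727072812301001,
  "G0007": 8.675694655253897,
  "G0008": 17.3203193337509,
  "G0009": 7.7624610126196,
  "G0010": 6.830162636833999,
  "G0011": 10.727031007225001,
  "G0012": 13.5795842432305,
  "G0013": 9.780282025233097,
  "G0014": 9.828828926983006,
  "G0015": 9.8919431529458,
  "G0016": 17.49803072213,
  "G0017": 4.832814227221999,
  "G0018": 17.5540983547974,
  "G0019": 1.0139289079935003,
  "G0020": 3.9348527329149996,
  "G0021": 8.762916836972002,
  "G0022": 18.514200259728206,
  "G0023": 3.9299055730949997,
  "G0024": 21.458058711027505,
  "G0025": 13.726669673027,
  "G0026": 10.652327297633,
  "G0027": 9.751940303943002,
  "G0028": 8.635330992157002,
  "G0029": 24.312637865743,
  "G0030": 15.560369819321998,
  "G0031": 11.724142291703,
  "G0032": 13.587779897792,
  "G0033": 17.590224711197003,
  "G0034": 23.419848932873002,
  "G0035": 24.334159738334996,
  "G0036": 14.551931391236,
  "G0037": 8.66386721093,
  "G0038": 20.402622037687,
  "G0039": 12.662015363775,
  "G0040": 14.646847512432,
  "G0041": 6.873359904095,
  "G0042": 15.581083587609001,
  "G0043": 15.652127856798,
  "G0044": 20.572330664721
 },
 "gained_lost": {
  "conformation": {
   "gained": [
    "G0030",
    "G0031",
    "G0032",
    "G0033",
    "G0034",
    "G0035",
    "G0036",
    "G0037",
    "G0038",
    "G0039",
    "G0040",
    "G0041",
    "G0042",
    "G0043",
    "G0044"
   ],
   "lost": []
  },
  "interaction": {
   "gained": [
    "G0018",
    "G0020",
    "G0023",
    "G0030",
    "G0031",
    "G0032",
    "G0033",
    "G0034",
    "G0035",
    "G0036",
    "G0037",
    "G0038",
    "G0039",
    "G0040",
    "G0041",
    "G0042",
    "G0043",
    "G0044"
   ],
   "lost": []
  },
  "similarity": {
   "gained": [
    "G0030",
    "G0031",
    "G0032",
    "G0033",
    "G0034",
    "G0035",
    "G0036",
    "G0037",
    "G0038",
    "G0039",
    "G0040",
    "G0041",
    "G0042",
    "G0043",
    "G0044"
   ],
   "lost": []
  }
 },
 "post": "post",
 "pre": "pre",
 "schema_version": "1",
 "signature_flags": {
  "post_denser_conformation": true,
  "post_more_drivers": true,
  "post_more_genes": true,
  "post_seed_conformation_degree_higher": true
 }
}
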