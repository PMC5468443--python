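# The six-entity mTOR-associated biological regulatory network.
# State vectors follow the order PI3K, PTEN, mTORC2, Akt, mTORC1, FOXO.
# `range` lists the admissible focal levels for each logical parameter
# K_target(resources); `selected` is the retained parameterization.
entities:
  - {name: PI3K,   max: 1}
  - {name: PTEN,   max: 1}
  - {name: mTORC2, max: 1}
  - {name: Akt,    max: 1}
  - {name: mTORC1, max: 1}
  - {name: FOXO,   max: 1}
interactions:
  - {source: PTEN,   target: PI3K,   sign: "-", threshold: 1}
  - {source: mTORC1, target: PI3K,   sign: "-", threshold: 1}
  - {source: PI3K,   target: PTEN,   sign: "-", threshold: 1}
  - {source: PI3K,   target: mTORC2, sign: "+", threshold: 1}
  - {source: FOXO,   target: mTORC2, sign: "+", threshold: 1}
  - {source: mTORC1, target: mTORC2, sign: "-", threshold: 1}
  - {source: PI3K,   target: Akt,    sign: "+", threshold: 1}
  - {source: mTORC2, target: Akt,    sign: "+", threshold: 1}
  - {source: Akt,    target: mTORC1, sign: "+", threshold: 1}
  - {source: FOXO,   target: mTORC1, sign: "-", threshold: 1}
  - {source: Akt,    target: FOXO,   sign: "-", threshold: 1}
  - {source: mTORC1, target: FOXO,   sign: "-", threshold: 1}
parameters:
  - {target: PI3K,   resources: [],               range: [0]}
  - {target: PI3K,   resources: [mTORC1],         range: [0, 1]}
  - {target: PI3K,   resources: [PTEN],           range: [0, 1]}
  - {target: PI3K,   resources: [mTORC1, PTEN],   range: [0, 1]}
  - {target: PTEN,   resources: [],               range: [0]}
  - {target: PTEN,   resources: [PI3K],           range: [1]}
  - {target: mTORC2, resources: [],               range: [0]}
  - {target: mTORC2, resources: [FOXO],           range: [0, 1]}
  - {target: mTORC2, resources: [mTORC1],         range: [1]}
  - {target: mTORC2, resources: [PI3K],           range: [0, 1]}
  - {target: mTORC2, resources: [FOXO, mTORC1],   range: [1]}
  - {target: mTORC2, resources: [FOXO, PI3K],     range: [0, 1]}
  - {target: mTORC2, resources: [mTORC1, PI3K],   range: [1]}
  - {target: mTORC2, resources: [FOXO, mTORC1, PI3K], range: [1]}
  - {target: Akt,    resources: [],               range: [0]}
  - {target: Akt,    resources: [mTORC2],         range: [0]}
  - {target: Akt,    resources: [PI3K],           range: [0]}
  - {target: Akt,    resources: [mTORC2, PI3K],   range: [1]}
  - {target: mTORC1, resources: [],               range: [0]}
  - {target: mTORC1, resources: [Akt],            range: [0, 1]}
  - {target: mTORC1, resources: [FOXO],           range: [1]}
  - {target: mTORC1, resources: [Akt, FOXO],      range: [1]}
  - {target: FOXO,   resources: [],               range: [0]}
  - {target: FOXO,   resources: [Akt],            range: [1]}
  - {target: FOXO,   resources: [mTORC1],         range: [0]}
  - {target: FOXO,   resources: [Akt, mTORC1],    range: [1]}
selected:
  - {target: PI3K,   resources: [],               value: 0}
  - {target: PI3K,   resources: [mTORC1],         value: 1}
  - {target: PI3K,   resources: [PTEN],           value: 1}
  - {target: PI3K,   resources: [mTORC1, PTEN],   value: 1}
  - {target: PTEN,   resources: [],               value: 0}
  - {target: PTEN,   resources: [PI3K],           value: 1}
  - {target: mTORC2, resources: [],               value: 0}
  - {target: mTORC2, resources: [FOXO],           value: 1}
  - {target: mTORC2, resources: [mTORC1],         value: 1}
  - {target: mTORC2, resources: [PI3K],           value: 1}
  - {target: mTORC2, resources: [FOXO, mTORC1],   value: 1}
  - {target: mTORC2, resources: [FOXO, PI3K],     value: 1}
  - {target: mTORC2, resources: [mTORC1, PI3K],   value: 1}
  - {target: mTORC2, resources: [FOXO, mTORC1, PI3K], value: 1}
  - {target: Akt,    resources: [],               value: 0}
  - {target: Akt,    resources: [mTORC2],         value: 0}
  - {target: Akt,    resources: [PI3K],           value: 0}
  - {target: Akt,    resources: [mTORC2, PI3K],   value: 1}
  - {target: mTORC1, resources: [],               value: 0}
  - {target: mTORC1, resources: [Akt],            value: 0}
  - {target: mTORC1, resources: [FOXO],           value: 1}
  - {target: mTORC1, resources: [Akt, FOXO],      value: 1}
  - {target: FOXO,   resources: [],               value: 0}
  - {target: FOXO,   resources: [Akt],            value: 1}
  - {target: FOXO,   resources: [mTORC1],         value: 0}
  - {target: FOXO,   resources: [Akt, mTORC1],    value: 1}
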