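compartments: [serum, liver, heart, vastus, adipose, brain]
edges:
  - [serum, liver]
  - [serum, heart]
  - [serum, vastus]
  - [serum, adipose]
  - [serum, brain]
termini:
  liver: "synthesis; fatty acid oxidation"
  brain: "structural (CNS)"
  heart: "fatty acid oxidation"
  vastus: "fatty acid oxidation"
  adipose: "storage"
  serum: "transport hub"
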