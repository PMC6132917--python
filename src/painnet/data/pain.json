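{
 "name": "pain",
 "n_total": 264,
 "indices": [
  4,
  17,
  33,
  52,
  68,
  140,
  151,
  163,
  176,
  188,
  201,
  215,
  227,
  239,
  250,
  261
 ],
 "labels": [
  "vermis cerebellum",
  "anterior/mid insula (right)",
  "superior temporal gyrus",
  "calcarine gyrus",
  "ventrolateral thalamus (right)",
  "mid insula (left)",
  "hypothalamus",
  "ventrolateral thalamus (left)",
  "frontal operculum/temporal pole",
  "dorsal posterior insula/secondary somatosensory area (left)",
  "dorsal posterior insula (right)",
  "somatosensory area (right)",
  "temporoparietal junction",
  "dorsal anterior cingulate cortex",
  "supramarginal gyrus",
  "inferior parietal lobule"
 ],
 "comment": "16-node pain network: positive-predictive-weight regions of the neural pain signature. Region names are authoritative; the atlas INDEX assignments below are documented placeholders (the published index table is not bundled) - edit this file to substitute the exact indices. 0-based positions into the whole-brain ordering."
}
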