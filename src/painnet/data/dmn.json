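{
 "name": "dmn",
 "n_total": 264,
 "indices": [
  74,
  75,
  76,
  77,
  78,
  79,
  80,
  81,
  82,
  83,
  84,
  85,
  86,
  87,
  88,
  89,
  90,
  91,
  92,
  93,
  94,
  95,
  96,
  97,
  98,
  99,
  100,
  101,
  102,
  103,
  104,
  105,
  106,
  107,
  108,
  109,
  110,
  111,
  112,
  113,
  114,
  115,
  116,
  117,
  118,
  119,
  120,
  121,
  122,
  123,
  124,
  125,
  126,
  127,
  128,
  129,
  130,
  131
 ],
 "comment": "58-node default mode network. The contiguous index block is a documented placeholder for the published DMN community assignment - edit to substitute exact indices. 0-based positions into the whole-brain ordering."
}
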