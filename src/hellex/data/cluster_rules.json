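{
 "phones": {
  "p":  {"moa": 1, "poa": 1, "voiced": false, "manner": "stop"},
  "b":  {"moa": 1, "poa": 1, "voiced": true,  "manner": "stop"},
  "t":  {"moa": 1, "poa": 2, "voiced": false, "manner": "stop"},
  "d":  {"moa": 1, "poa": 2, "voiced": true,  "manner": "stop"},
  "c":  {"moa": 1, "poa": 3, "voiced": false, "manner": "stop"},
  "k":  {"moa": 1, "poa": 4, "voiced": false, "manner": "stop"},
  "g":  {"moa": 1, "poa": 4, "voiced": true,  "manner": "stop"},
  "ts": {"moa": 2, "poa": 2, "voiced": false, "manner": "affricate"},
  "dz": {"moa": 2, "poa": 2, "voiced": true,  "manner": "affricate"},
  "f":  {"moa": 3, "poa": 1, "voiced": false, "manner": "fricative"},
  "v":  {"moa": 3, "poa": 1, "voiced": true,  "manner": "fricative"},
  "θ":  {"moa": 3, "poa": 2, "voiced": false, "manner": "fricative"},
  "δ":  {"moa": 3, "poa": 2, "voiced": true,  "manner": "fricative"},
  "s":  {"moa": 3, "poa": 2, "voiced": false, "manner": "fricative"},
  "z":  {"moa": 3, "poa": 2, "voiced": true,  "manner": "fricative"},
  "ç":  {"moa": 3, "poa": 3, "voiced": false, "manner": "fricative"},
  "ʝ":  {"moa": 3, "poa": 3, "voiced": true,  "manner": "fricative"},
  "x":  {"moa": 3, "poa": 4, "voiced": false, "manner": "fricative"},
  "γ":  {"moa": 3, "poa": 4, "voiced": true,  "manner": "fricative"},
  "m":  {"moa": 4, "poa": 1, "voiced": true,  "manner": "nasal"},
  "ɱ":  {"moa": 4, "poa": 1, "voiced": true,  "manner": "nasal"},
  "n":  {"moa": 4, "poa": 2, "voiced": true,  "manner": "nasal"},
  "ɲ":  {"moa": 4, "poa": 3, "voiced": true,  "manner": "nasal"},
  "ŋ":  {"moa": 4, "poa": 4, "voiced": true,  "manner": "nasal"},
  "l":  {"moa": 5, "poa": 2, "voiced": true,  "manner": "liquid"},
  "r":  {"moa": 5, "poa": 2, "voiced": true,  "manner": "liquid"},
  "ʎ":  {"moa": 5, "poa": 3, "voiced": true,  "manner": "liquid"}
 },
 "whitelist": [],
 "heterosyllabic_overrides": ["liquid-initial", "nasal+liquid"],
 "strict_nasal_liquid": true,
 "voicing_split": true
}
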