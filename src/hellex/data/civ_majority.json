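{
 "ιο": [3, 17],
 "ια": [12, 8],
 "ιε": [5, 15],
 "ιω": [12, 8],
 "ιου": [6, 14],
 "υα": [8, 12],
 "υο": [10, 10],
 "ειο": [12, 8],
 "εια": [12, 8],
 "οια": [14, 6],
 "ηα": [2, 18]
}
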