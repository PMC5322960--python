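# CiV exception lexicon: word <TAB> one|two (applies to all sites of the word)
γυαλα	one
νιωθω	one
διαβατης	one
κλεψια	one
διαφανος	one
καρδια	one
ποιος	one
κυανιο	two
αγωνιω	two
ελεγκτρια	two
βιολι	two
θεια	one
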