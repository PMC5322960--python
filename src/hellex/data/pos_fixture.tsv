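# synthetic fixture dictionary for tests and examples: word <TAB> tags (first = headword category)
γέρος	noun
πατέρας	noun
θάλασσα	noun
άνθρωπος	noun
καμβάς	noun
γυάλα	noun
νιώθω	verb
διαβάτης	noun
κυάνιο	noun
αντένα	noun
κλεψιά	noun
ελέγκτρια	noun
επάξια	adverb,adjective
ωραίος	adjective
γράφω	verb
τραχεία	adjective,noun
μασκοφόρος	noun,adjective
και	conjunction
ο	article
θρόνος	noun
στρατός	noun
άρμα	noun
άρπα	noun
αέρας	noun
καρδιά	noun
ποιος	pronoun
βιολί	noun
διάφανος	adjective
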