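["β", "γ", "δ", "ζ", "θ", "κ", "λ", "μ", "ν", "ξ", "π", "ρ", "σ", "τ", "φ", "χ", "ψ",
 "βγ", "βδ", "βλ", "βρ", "γδ", "γκ", "γλ", "γν", "γρ", "δρ", "θλ", "θν", "θρ",
 "κβ", "κλ", "κν", "κρ", "κτ", "μν", "μπ", "ντ", "πλ", "πν", "πρ", "πτ",
 "σβ", "σθ", "σκ", "σμ", "σπ", "στ", "σφ", "σχ", "τζ", "τμ", "τρ", "τσ",
 "φθ", "φλ", "φρ", "φτ", "χλ", "χν", "χρ", "χτ",
 "γκλ", "γκρ", "μπλ", "μπρ", "ντρ", "σκλ", "σκν", "σκρ", "σπλ", "σπρ", "στρ", "σφρ"]
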