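# Default taxon exclusion list: groups commonly recorded inconsistently
# because of small size, plus terrestrial/semi-aquatic taxa and vertebrates.
# Matched against taxon ids and any taxonomy rank name. Replace with a
# provider-specific list via --exclusion-list / the exclusions argument.
Hydrachnidia
Acari
Copepoda
Cladocera
Ostracoda
Collembola
Vertebrata
Pisces
Amphibia
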