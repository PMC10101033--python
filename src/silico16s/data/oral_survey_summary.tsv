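domain	total_species	single_copy_species
bacteria	186	11
archaea	135	64
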