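# Miyata-style classification by polarity and volume (six groups).
special: C
small_polar: AGPST
polar: NDQE
basic: RHK
large_nonpolar: ILMV
aromatic: FWY
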