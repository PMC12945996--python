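# canonical generic name, synonym (generic or brand spelling)
canonical,synonym
Avatrombopag,Avatrombopag
Avatrombopag,Doptelet
Eltrombopag,Eltrombopag
Eltrombopag,Eltrombopag olamine
Eltrombopag,Promacta
Eltrombopag,Revolade
Romiplostim,Romiplostim
Romiplostim,Nplate
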