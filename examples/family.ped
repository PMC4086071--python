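FAM1 FATHER 0 0 1 1
FAM1 MOTHER 0 0 2 1
FAM1 PROBAND FATHER MOTHER 1 2
FAM1 SIBLING FATHER MOTHER 2 1
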