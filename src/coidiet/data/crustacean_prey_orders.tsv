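order	count
Decapoda	40
Stomatopoda	2
Euphausiacea	1
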