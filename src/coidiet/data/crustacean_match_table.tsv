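order	family	genus	species	similarity_pct
Decapoda	Alpheidae	Synalpheus		99.24
Decapoda	Hyppolytidae	Thor		93.18
Decapoda	Palaemonidae			88
Decapoda	Palaemonidae			88.24
Decapoda				84.30
Decapoda				84
Decapoda				85.71
Decapoda				86.2
Decapoda				85.63
Decapoda				85.34
Decapoda				83.3
Decapoda				82.83
Decapoda				82.82
Decapoda				96.52
Decapoda
Decapoda				79.22
Euphausiacea	Euphausiidae	Euphausia	Euphausia americana	100
Stomatopoda	Gonodactylidae			87.2
Stomatopoda	Pseudosquillidae	Pseudosquilla		95.39
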