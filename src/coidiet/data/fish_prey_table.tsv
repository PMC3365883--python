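order	family	genus	species	count	similarity_pct
Beryciformes	Holocentridae	Sargocentron	Sargocentron coruscum	1	100
Perciformes	Apogonidae	Apogon	Apogon lachneri	2	100
Perciformes	Apogonidae	Apogon	Apogon maculatus	2	100
Perciformes	Apogonidae	Apogon	Apogon mosavi	1	99.68
Perciformes	Apogonidae	Apogon	Apogon townsendi	2	100
Perciformes	Apogonidae	Astrapogon		1
Perciformes	Apogonidae	Astrapogon	Astrapogon puncticulatus	1	99.84
Perciformes	Gobiidae	Coryphopterus	Coryphopterus venezuelae	6	99.69
Perciformes	Gobiidae	Coryphopterus	Coryphopterus eidolon	2	100
Perciformes	Gobiidae	Coryphopterus	Coryphopterus hyalinus	2	100
Perciformes	Gobiidae	Coryphopterus	Coryphopterus thrix	2	99.85
Perciformes	Gobiidae	Coryphopterus	Coryphopterus tortugae	6	100
Perciformes	Gobiidae	Priolepis	Priolepis hipoliti	1	99.69
Perciformes	Gobiidae	Lythrypnus	Lythrypnus minimus	6	99
Perciformes	Grammatidae	Gramma	Gramma loreto	3	99.84
Perciformes	Haemulidae	Haemulon	Haemulon flavolineatum	3	100
Perciformes	Labridae	Halichoeres	Halichoeres garnoti	22	100
Perciformes	Labridae	Thalassoma	Thalassoma bifasciatum	11	100
Perciformes	Labrisomidae	Malacoctenus	Malacoctenus triangulatus	2	99.69
Perciformes	Labrisomidae	Starksia	Starksia ocellata	1	99.38
Perciformes	Labrisomidae	Starksia	Starksia langi	1	99
Perciformes	Pomacentridae	Abudefduf	Abudefduf saxatilis	1	100
Perciformes	Pomacentridae	Stegastes	Stegastes partitus	6	99.85
Perciformes	Scaridae	Scarus	Scarus iseri	2	100
Perciformes	Scaridae	Scarus	Scarus taeniopterus	1	100
Perciformes	Scaridae	Sparisoma	Sparisoma aurofrenatum	8	100
Perciformes	Scaridae	Sparisoma	Sparisoma viride	2	100
Perciformes	Serranidae	Cephalopholis	Cephalopholis cruentata	3	100
Perciformes	Serranidae	Liopropoma	Liopropoma rubre	2	100
Perciformes	Tripterygiidae	Enneanectes	Enneanectes altivelis	3	100
Perciformes	Tripterygiidae	Enneanectes	Enneanectes boehlkei	1	100
Pleuronectiformes	Bothidae	Bothus	Bothus lunatus	1	100
Scorpaeniformes	Scorpaenidae	Pterois	Pterois volitans	16	100
Tetraodontiformes	Monacanthidae	Monacanthus	Monacanthus tuckeri	1	100
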