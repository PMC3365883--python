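# Fish species previously reported from the Mexican Caribbean among the
# prey roster (regional prior checklist used for new-record flagging).
Sargocentron coruscum
Apogon lachneri
Apogon maculatus
Apogon townsendi
Astrapogon puncticulatus
Coryphopterus eidolon
Coryphopterus hyalinus
Priolepis hipoliti
Gramma loreto
Haemulon flavolineatum
Halichoeres garnoti
Thalassoma bifasciatum
Malacoctenus triangulatus
Abudefduf saxatilis
Stegastes partitus
Scarus iseri
Scarus taeniopterus
Sparisoma aurofrenatum
Sparisoma viride
Cephalopholis cruentata
Liopropoma rubre
Enneanectes altivelis
Enneanectes boehlkei
Bothus lunatus
Pterois volitans
Monacanthus tuckeri
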