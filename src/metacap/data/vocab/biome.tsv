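term_id	label	synonyms	parents
ENVO:00000428	biome
ENVO:00002030	aquatic biome		ENVO:00000428
ENVO:00000447	marine biome	ocean biome	ENVO:00002030
ENVO:00000873	freshwater biome		ENVO:00002030
ENVO:01000023	estuarine biome	brackish biome	ENVO:00002030
ENVO:00000446	terrestrial biome		ENVO:00000428
ENVO:01000174	forest biome	woodland biome	ENVO:00000446
ENVO:01000177	grassland biome	savanna biome	ENVO:00000446
ENVO:01000179	desert biome	arid biome	ENVO:00000446
ENVO:01000180	tundra biome		ENVO:00000446
ENVO:01000219	anthropogenic terrestrial biome	human-made terrestrial biome	ENVO:00000446
ENVO:01000339	polar biome		ENVO:00000428
ENVO:01000048	mangrove biome		ENVO:00002030
ENVO:01000252	freshwater lake biome	lake biome	ENVO:00000873
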