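term_id	label	synonyms	parents
ENVO:00000015	ocean
ENVO:00000016	sea
ENVO:00000020	lake
ENVO:00000022	river
ENVO:00000023	stream	creek|brook
ENVO:00000045	estuary
ENVO:00000043	wetland	marsh area
ENVO:00000091	beach
ENVO:00000133	glacier
ENVO:00000150	coral reef	reef
ENVO:00000215	hydrothermal vent	deep-sea vent
ENVO:00000292	watershed	drainage basin
ENVO:00002040	agricultural field	farm field|cropland
ENVO:00000114	meadow
ENVO:00000111	forest ecosystem	forested area
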