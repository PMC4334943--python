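term_id	label	synonyms	parents
ENVO:00002006	water	aqueous substance
ENVO:00002149	sea water	seawater|salt water	ENVO:00002006
ENVO:00002011	fresh water	freshwater	ENVO:00002006
ENVO:00002001	waste water	wastewater|sewage water	ENVO:00002006
ENVO:00001998	soil
ENVO:00005774	peat soil	peat	ENVO:00001998
ENVO:00002007	sediment
ENVO:00002113	marine sediment	sea floor sediment	ENVO:00002007
ENVO:00002005	air	atmosphere gas
ENVO:00002044	sludge
ENVO:00002034	biofilm	microbial mat
ENVO:00002170	compost
ENVO:01000017	sand
ENVO:00002982	clay
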