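term_id	label	synonyms	parents
EP:0000001	air
EP:0000002	built environment	built-environment
EP:0000003	host-associated	host associated
EP:0000004	human-associated	human associated
EP:0000005	human-gut	human gut
EP:0000006	human-oral	human oral
EP:0000007	human-skin	human skin
EP:0000008	human-vaginal	human vaginal
EP:0000009	microbial mat	biofilm package
EP:0000010	miscellaneous	miscellaneous natural or artificial environment
EP:0000011	plant-associated	plant associated
EP:0000012	sediment
EP:0000013	soil
EP:0000014	wastewater	wastewater/sludge
EP:0000015	water
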