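order,family,genus,species,count,status
Poales,Poaceae,Eleusine,Eleusine indica,160,Non-native; invasive
Fagales,Casuarinaceae,Casuarina,Casuarina equisetifolia,155,Non-native; invasive
Caryophyllales,Chenopodiaceae,Chenopodium,Chenopodium album,100,Native
Brassicales,Brassicaceae,Lobularia,Lobularia maritima,59,Non-native; naturalized
Boraginales,Heliotropiaceae,Tournefortia,Tournefortia argentea,53,Non-native; naturalized
Solanales,Convolvulaceae,Ipomoea,Ipomoea pes-caprae,45,Native
Caryophyllales,Nyctaginaceae,Boerhavia,Boerhavia repens,43,Native
Lamiales,Verbenaceae,Phyla,Phyla nodiflora,38,Non-native; naturalized
Poales,Poaceae,Eragrostis,Eragrostis sp.,20,N/A
Solanales,Solanaceae,Solanum,Solanum nigrum,20,Native
Poales,Poaceae,Stenotaphrum,Stenotaphrum secundatum,18,Non-native; naturalized
Asterales,Goodeniaceae,Scaevola,Scaevola taccada,15,Native
Caryophyllales,Aizoaceae,Sesuvium,Sesuvium portulacastrum,14,Native
Caryophyllales,Caryophyllaceae,Spergularia,Spergularia sp.,11,Non-native
Poales,Poaceae,Cynodon,Cynodon aristulatus,10,Non-native
Boraginales,Heliotropiaceae,Euploca,Euploca campestris,8,Non-native
Poales,Poaceae,Eragrostis,Eragrostis tenella,7,Non-native; naturalized
Brassicales,Brassicaceae,Lepidium,Lepidium angustissimum,7,Non-native
Asterales,Asteraceae,Conyza,Conyza sp.,6,Non-native; invasive
Malpighiales,Euphorbiaceae,Euphorbia,Euphorbia sp.,6,Non-native; naturalized
Poales,Poaceae,Cynodon,Cynodon sp.,5,Non-native
Poales,Cyperaceae,Cyperus,Cyperus polystachyos,4,Native
Poales,Poaceae,Sporobolus,Sporobolus pyramidatus,4,Non-native; naturalized
Asterales,Asteraceae,Erigeron,Erigeron canadensis,4,Non-native; invasive
Caryophyllales,Caryophyllaceae,Spergularia,Spergularia media,4,Non-native
Myrtales,Combretaceae,Terminalia,Terminalia catappa,4,Non-native; naturalized
Solanales,Convolvulaceae,Ipomoea,Ipomoea indica,4,Native
Boraginales,Heliotropiaceae,Euploca,Euploca sp.,3,Non-native
Poales,Poaceae,Cynodon,Cynodon nlemfuensis,2,Non-native
Poales,Poaceae,Dactyloctenium,Dactyloctenium aegyptium,2,Non-native; invasive
Poales,Poaceae,Eustachys,Eustachys sp.,2,Non-native
Asterales,Asteraceae,Pseudognaphalium,Pseudognaphalium sp.,2,Native
Brassicales,Brassicaceae,Lepidium,Lepidium virginicum,2,Non-native; naturalized
Caryophyllales,Amaranthaceae,Amaranthus,Amaranthus spinosus,2,Non-native; invasive
Caryophyllales,Amaranthaceae,Amaranthus,Amaranthus viridis,2,Non-native; naturalized
Malpighiales,Euphorbiaceae,Euphorbia,Euphorbia peplus,2,Non-native; naturalized
Rosales,Urticaceae,Urtica,Urtica dioica,2,Non-native
Poales,Cyperaceae,Cyperus,Cyperus sp.,1,N/A
Poales,Poaceae,Digitaria,Digitaria sp.,1,Non-native
Poales,Poaceae,Ectrosia,Ectrosia sp.,1,Non-native
Poales,Poaceae,Hordeum,Hordeum sp.,1,Non-native
Poales,Poaceae,Poa,Poa annua,1,Non-native; naturalized
Poales,Poaceae,Sporobolus,Sporobolus virginicus,1,Native
Apiales,Apiaceae,Cyclospermum,Cyclospermum leptophyllum,1,Non-native; naturalized
Asterales,Asteraceae,Bidens,Bidens alba,1,Non-native; invasive
Caryophyllales,Chenopodiaceae,Atriplex,Atriplex suberecta,1,Non-native; naturalized
Fabales,Fabaceae,Glycine,Glycine max,1,Non-native; naturalized
Myrtales,Onagraceae,Oenothera,Oenothera sp.,1,Non-native
Rosales,Cannabaceae,Humulus,Humulus sp.,1,Non-native
Solanales,Convolvulaceae,Ipomoea,Ipomoea sp.,1,N/A
Solanales,Convolvulaceae,Ipomoea,Ipomoea nil,1,Non-native
Solanales,Solanaceae,Solanum,Solanum sp.,1,N/A
Zygophyllales,Zygophyllaceae,Tribulus,Tribulus terrestris,1,Native
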