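order,family,genus,species,count,status
Isopoda,Porcellionidae,Porcellionides,Porcellionides pruinosus,199,Non-native
Isopoda,Porcellionidae,Porcellio,Porcellio laevis,177,Non-native
Hymenoptera,Formicidae,Monomorium,Monomorium bicolor complex BOLD:AAB9999,150,Non-native
Hymenoptera,Formicidae,Tetramorium,Tetramorium bicarinatum,144,Non-native
Diptera,Calliphoridae,Lucilia,Lucilia sericata,127,Non-native
Diptera,Sarcophagidae,Sarcophaga,Sarcophaga dux,116,Non-native
Ixodida,Argasidae,Ornithodoros,Ornithodoros capensis,113,N/A (circumglobal distribution)
Blattodea,Blattidae,Periplaneta,Periplaneta sp.,104,Non-native
Hymenoptera,Formicidae,Tetramorium,Tetramorium caldarium,61,Non-native
Diptera,Phoridae,Megaselia,Megaselia scalaris,40,Non-native
Araneae,Gnaphosidae,Trachyzelotes,Trachyzelotes jaxartensis,35,Non-native
Lepidoptera,Plutellidae,Plutella,Plutella xylostella,24,Non-native
Lepidoptera,Tortricidae,Olethreutes,Olethreutes sp.,24,Non-native
Lepidoptera,Noctuidae,Chrysodeixis,Chrysodeixis eriosoma,14,Non-native
Lepidoptera,Tineidae,Praeacedes,Praeacedes atomosella,13,Non-native
Lepidoptera,Saturniidae,Archaeoattacus,Archaeoattacus edwardsii,12,Non-native
Isopoda,Armadillidae,Cubaris,Cubaris murina,12,Non-native
Lepidoptera,Crambidae,Hellula,Hellula undalis,7,Non-native
Thysanoptera,Thripidae,Arorathrips,Arorathrips mexicanus,6,Non-native
Coleoptera,Dermestidae,Dermestes,Dermestes ater,5,Native
Diptera,Muscidae,Muscidae incertae sedis,Muscidae sp. BOLD:AAN8579,5,Non-native
Hemiptera,Membracidae,Vanduzea,Vanduzea sp. n. LA,5,Non-native
Coleoptera,Elateridae,Heteroderes,Heteroderes kusuii,4,Non-native
Lepidoptera,Noctuidae,Mythimna,Mythimna loreyi,4,Non-native
Psocoptera,Psocoptera incertae sedis,Psocoptera incertae sedis,Psocoptera sp. BOLD:ACB0983,4,Non-native
Coleoptera,Curculionidae,Sphenophorus,Sphenophorus venatus,3,Non-native
Coleoptera,Silvanidae,Oryzaephilus,Oryzaephilus surinamensis,3,Non-native
Diptera,Calliphoridae,Chrysomya,Chrysomya megacephala,3,Non-native
Lepidoptera,Autostichidae,Stoeberhinus,Stoeberhinus testaceus,3,Non-native
Thysanoptera,Thripidae,Frankliniella,Frankliniella sp.,3,Non-native
Blattodea,Blattidae,Periplaneta,Periplaneta americana,2,Non-native
Thysanoptera,Phlaeothripidae,Haplothrips,Haplothrips sp.,2,Non-native
Araneae,Nesticidae,Eidmannella,Eidmannella sp. 1579,1,Non-native
Araneae,Salticidae,Hasarius,Hasarius adansoni,1,Non-native
Diplostraca,Macrotrichidae,Macrothrix,Macrothrix sp. HE-364,1,Non-native
Blattodea,Rhinotermitidae,Coptotermes,Coptotermes formosanus,1,Non-native
Coleoptera,Anthribidae,Araecerus,Araecerus fasciculatus,1,Non-native
Coleoptera,Curculionidae,Asynonychus,Asynonychus cervinus,1,Non-native
Coleoptera,Dermestidae,Dermestes,Dermestes maculatus,1,Native
Diptera,Chironomidae,Polypedilum,Polypedilum nubiferum,1,Non-native
Diptera,Drosophilidae,Drosophilidae incertae sedis,Drosophilinae sp. BOLD:AAG8493,1,Non-native
Diptera,Muscidae,Thricops,Thricops cunctans,1,Non-native
Diptera,Sciaridae,Sciaridae incertae sedis,Sciaridae sp. JEF,1,Non-native
Hemiptera,Cicadellidae,Cicadellidae incertae sedis,Cicadellidae sp. 3 AY-2015,1,Non-native
Hemiptera,Cicadellidae,Neoaliturus,Neoaliturus tenellus,1,Non-native
Hemiptera,Coccidae,Coccus,Coccus viridis,1,Non-native
Hemiptera,Delphacidae,Toya,Toya sp. BOLD:AAF8686,1,Non-native
Hymenoptera,Braconidae,Chelonus,Chelonus blackburni,1,Non-native
Hymenoptera,Formicidae,Plagiolepis,Plagiolepis alluaudi,1,Non-native
Hymenoptera,Vespidae,Polistes,Polistes jokahamae,1,Non-native
Lepidoptera,Noctuidae,Spodoptera,Spodoptera mauritia,1,Non-native
Lepidoptera,Tineidae,Tineidae incertae sedis,Tineidae sp. PTO-847.19,1,Non-native
Psocoptera,Liposcelidae,Liposcelis,Liposcelis decolor,1,Non-native
Psocoptera,Liposcelidae,Liposcelis,Liposcelis entomophila,1,Non-native
Decapoda,Decapoda incertae sedis,Decapoda incertae sedis,Brachyura sp. LPdivOTU430,1,N/A; not enough data
Cyclopoida,Cyclopoida incertae sedis,Cyclopoida incertae sedis,Cyclopoida sp. HE-372.1,1,N/A; not enough data
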