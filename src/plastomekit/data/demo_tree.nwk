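((Lolium_perenne,Zizania_aquatica),((((Acidosasa_purpurea,(Arundinaria_appalachiana,(Arundinaria_gigantea,Arundinaria_tecta))),Ferrocalamus_rimosivaginus),(((Phyllostachys_edulis,(Phyllostachys_nigra,Phyllostachys_propinqua)),Indocalamus_longiauritus),Thamnocalamus_spathiflorus)),((((Chusquea_spectabilis,Chusquea_liebmannii),(Guadua_weberbaueri,(Olmeca_reflexa,Otatea_acuminata))),(Hickelia_madagascariensis,(((Bambusa_bambos,(Bambusa_arnhemica,(Bambusa_emeiensis,Bambusa_oldhamii))),Dendrocalamus_latiflorus),(Neololeba_atra,Greslania_sp)))),(Buergersiochloa_bambusoides,((Cryptochloa_strictiflora,(Diandrolyra_sp,(Lithachne_pauciflora,(Olyra_latifolia,Raddia_brasiliensis)))),(Eremitis_sp,Pariana_radiciflora))))));
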