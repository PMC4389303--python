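event	kind	locus	length_bp	clade	taxa	notes
parianinae_shared_insert	insertion	rpl23-ndhB	2706	Parianinae	Eremitis sp.;Pariana radiciflora	mitochondrial-like sequence within the IR
parianinae_3prime_extension	insertion	rpl23-ndhB	2232	Parianinae	Eremitis sp.	appended 3' of the shared insert; shared+extension = 4938 bp total; an alternative printed figure of 1242 bp is arithmetically inconsistent with that total
guaduinae_deletion	deletion	rpl23-ndhB	1500	Guaduinae	Guadua weberbaueri;Olmeca reflexa;Otatea acuminata	approximately the same region as the Parianinae insert
olyrinae_inversion	inversion	trnD-psbM	150	Olyrinae	Cryptochloa strictiflora;Diandrolyra sp.;Lithachne pauciflora;Olyra latifolia;Raddia brasiliensis	flanked by an imperfect 8 bp inverted repeat CCYTTTTY / GAAAAAGG
arundinarieae_insert	insertion	rps16-trnQ	500	Arundinarieae	Acidosasa purpurea;Arundinaria appalachiana;Arundinaria gigantea;Arundinaria tecta;Ferrocalamus rimosivaginus;Indocalamus longiauritus;Phyllostachys edulis;Phyllostachys nigra;Phyllostachys propinqua;Thamnocalamus spathiflorus	approximate length
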