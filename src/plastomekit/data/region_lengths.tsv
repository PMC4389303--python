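taxon	tribe	total_len	lsc_len	ssc_len	ir_len	accession	n_reads	library	sequencing	mean_coverage	n_contigs
Acidosasa purpurea	Arundinarieae	139697	83273	12834	21795	NC015820
Arundinaria appalachiana	Arundinarieae	139547	83222	12717	21804	NC023934
Arundinaria gigantea	Arundinarieae	138935	82632	12709	21797	NC020341
Arundinaria tecta	Arundinarieae	139499	83161	12730	21804	NC023935
Ferrocalamus rimosivaginus	Arundinarieae	139467	83091	12718	21829	NC015831
Indocalamus longiauritus	Arundinarieae	139668	83273	12811	21792	NC015803
Phyllostachys edulis	Arundinarieae	139679	83213	12870	21798	NC015817
Phyllostachys nigra	Arundinarieae	139839	83234	12879	21863	NC015826
Phyllostachys propinqua	Arundinarieae	139704	83228	12878	21799	NC016699
Thamnocalamus spathiflorus	Arundinarieae	139498	83310	12594	21797	KJ871005	7098663	TruSeq	single-end	54.8	5
Bambusa arnhemica	Bambuseae	139287	82790	12901	21798	KJ870989	2292120	TruSeq	single-end	25.7	15
Bambusa bambos	Bambuseae	142772	79972	12868	24966	KJ870988	5279202	TruSeq	single-end	53.2	3
Bambusa emeiensis	Bambuseae	139491	82976	12911	21802	NC015830
Bambusa oldhamii	Bambuseae	139347	82889	12878	21790	NC012927
Chusquea liebmannii	Bambuseae	138001	81501	12892	21804	KJ871001	23707569	TruSeq Nano	paired-end	126.8	6
Chusquea spectabilis	Bambuseae	136848	80743	12671	21717	KJ870990	7348756	Nextera	single-end	23.7	9
Dendrocalamus latiflorus	Bambuseae	139369	82975	12884	21755	NC013088
Greslania sp.	Bambuseae	139264	82581	12979	21852	KJ870993	13881568	Nextera	single-end	142.1	3
Guadua weberbaueri	Bambuseae	135320	82803	12929	19794	KP793062	29431971	Nextera	single-end	94.9	9
Hickelia madagascariensis	Bambuseae	138276	81925	12743	21804	KJ870994	13509970	Nextera	single-end	43.7	10
Neololeba atra	Bambuseae	139395	82905	12926	21782	KJ870996	28569106	TruSeq Nano	paired-end	497.3	13
Olmeca reflexa	Bambuseae	136213	82726	12945	20271	KJ870997	5400472	Nextera	single-end	51.3	6
Otatea acuminata	Bambuseae	136351	82859	12948	20272	KJ871003	14532488	TruSeq Nano	paired-end	134.9	4
Buergersiochloa bambusoides	Olyreae	138122	81746	12856	21760	KJ871000	12592122	Nextera	single-end	124.8	6
Cryptochloa strictiflora	Olyreae	134332	80554	12766	20506	JX235348
Diandrolyra sp.	Olyreae	137469	81752	13259	21229	KJ870991	10004619	Nextera	single-end	100	4
Eremitis sp.	Olyreae	143810	80984	13232	24797	KJ870992	4674178	Nextera	single-end	15.4	13
Lithachne pauciflora	Olyreae	135385	79465	13676	21122	KJ871002	14773417	Nextera	single-end	233.1	4
Olyra latifolia	Olyreae	135834	80642	12770	21211	KF515509
Pariana radiciflora	Olyreae	139650	81847	13221	22291	KJ871004	23398974	TruSeq Nano	paired-end	119.6	4
Raddia brasiliensis	Olyreae	135739	80713	13000	21013	KJ870998	6828240	Nextera	single-end	40.1	3
Zizania aquatica	Oryzeae (Ehrhartoideae)	136354	82009	12587	20879	KJ870999	6018945	TruSeq	single-end	66.3	3
Lolium perenne	Poeae (Pooideae)	135246	80000	12428	21409	NC009950
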