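snp_id	target_group	kk_piap	gaims	lace	other	appearance
rs10497191	AFR	Kiddlab		LACE		0
rs1197062	AFR		gAIMs	LACE		0
rs1369290	AFR		gAIMs			0
rs2789823	AFR		gAIMs			0
rs2814778	AFR	Kiddlab	gAIMs			0
rs310644	AFR	Kiddlab	gAIMs			0
rs4737753	AFR				NAME	0
rs11778591	EUR		gAIMs	LACE		0
rs12142199	EUR		gAIMs			0
rs12913832	EUR	Kiddlab	gAIMs			0
rs1426654	EUR	Kiddlab	gAIMs			0
rs16891982	EUR	Kiddlab	gAIMs			0
rs2715883	EUR		gAIMs			0
rs3759171	EUR		gAIMs	LACE		0
rs705308	EUR	PIAP				0
rs7084970	EUR		gAIMs			0
rs7531501	EUR		gAIMs			0
rs8072587	EUR		gAIMs			0
rs820371	EUR		gAIMs	LACE		0
rs862500	EUR		gAIMs	LACE		0
rs917115	EUR	Kiddlab	gAIMs			0
rs9522149	EUR	Kiddlab	gAIMs			0
rs10149275	OCE		gAIMs			0
rs16830500	OCE		gAIMs			0
rs2139931	OCE		gAIMs			0
rs2274636	OCE		gAIMs			0
rs26951	OCE		gAIMs			0
rs3751050	OCE		gAIMs			0
rs3804030	OCE		gAIMs			0
rs4391951	OCE		gAIMs			0
rs4959270	OCE				Pacifiplex	0
rs6054465	OCE		gAIMs			0
rs715605	OCE		gAIMs			0
rs9908046	OCE		gAIMs			0
rs9934011	OCE		gAIMs			0
rs10012227	AMR		gAIMs			0
rs10483251	AMR		gAIMs	LACE		0
rs12130799	AMR	PIAP				0
rs12498138	AMR	Kiddlab	gAIMs			0
rs12629908	AMR	PIAP				0
rs1452501	AMR		gAIMs	LACE		0
rs1557553	AMR		gAIMs	LACE		0
rs17130385	AMR		gAIMs	LACE		0
rs17359176	AMR		gAIMs	LACE		0
rs174570	AMR	Kiddlab	gAIMs	LACE		0
rs2302013	AMR		gAIMs			0
rs2471552	AMR		gAIMs			0
rs3737576	AMR	Kiddlab				0
rs4792928	AMR		gAIMs			0
rs5757362	AMR			LACE		0
rs8137373	AMR		gAIMs			0
rs870347	AMR	Kiddlab				0
rs10079352	EAS		gAIMs	LACE		0
rs1229984	EAS	Kiddlab	gAIMs			0
rs12594144	EAS		gAIMs			0
rs1371048	EAS		gAIMs			0
rs17822931	EAS		gAIMs			0
rs1834619	EAS	Kiddlab	gAIMs			0
rs2180052	EAS		gAIMs			0
rs3827760	EAS	Kiddlab	gAIMs			0
rs434504	EAS		gAIMs			0
rs459920	EAS	Kiddlab				0
rs4657449	EAS		gAIMs			0
rs4781011	EAS	PIAP				0
rs4918664	EAS	Kiddlab	gAIMs			0
rs4935501	EAS		gAIMs			0
rs7226659	EAS	Kiddlab				0
rs8104441	EAS		gAIMs			0
rs1040934	SAS				Shriver	0
rs1063677	SAS				Shriver	0
rs10764919	SAS			LACE		0
rs10962599	SAS				Eurasiaplex	0
rs13267318	SAS				Shriver	0
rs13280988	SAS			LACE		0
rs17625895	SAS				Eurasiaplex	0
rs1796048	SAS				Shriver	0
rs1924381	SAS		gAIMs	LACE		0
rs2026999	SAS				Shriver	0
rs2196051	SAS	Kiddlab			Eurasiaplex	0
rs2238151	SAS	Kiddlab				0
rs2269793	SAS	PIAP				0
rs2472304	SAS				Eurasiaplex	0
rs2503770	SAS		gAIMs	LACE		0
rs26247	SAS				Shriver	0
rs3844336	SAS				Shriver	0
rs7080350	SAS			LACE		0
rs7568054	SAS			LACE		0
rs756913	SAS				Eurasiaplex	0
rs1495085	EURASIA				NAME	0
rs1757928	EURASIA				NAME	0
rs2337024	EURASIA				NAME	0
rs6989963	EURASIA				NAME	0
rs6990312	EURASIA	Kiddlab				0
rs7148809	EURASIA				NAME	0
rs12203115	EURASIA				NAME	0
rs2227203	EURASIA				NAME	0
rs39897	EURASIA				Eurasiaplex	0
rs4308478	EURASIA				NAME	0
rs7570971	EURASIA				NAME	0
rs984038	EURASIA				NAME	0
rs6437783	EAS		gAIMs			1
rs1800414	EAS	Kiddlab				1
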