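parasite_lineage	parasite_rank	host_code	host_species	host_tribe	area_code	area_name	hydrological_system
Margotrema resolanae	species	m	Xenotaenia resolanae	Ilyodontini	I	Cuzalapa River	Cuzalapa River
Margotrema bravoae Lineage I	lineage	h	Codoma ornata	non-goodeid:Cyprinidae	A	Lower Conchos River	Conchos River Basin
Margotrema bravoae Lineage I	lineage	g	Allodontichthys zonistius	Ilyodontini	H	Armería-Ayuquila River	Ayuquila River
Margotrema bravoae Lineage I	lineage	k	Ilyodon furcidens	Ilyodontini	H	Armería-Ayuquila River	Ayuquila River
Margotrema bravoae Lineage I	lineage	j	Chapalichthys pardalis	Chapalichthyini	K	Lower Balsas River	Balsas River Basin
Margotrema bravoae Lineage I	lineage	l	Ilyodon whitei	Ilyodontini	K	Lower Balsas River	Balsas River Basin
Margotrema bravoae Lineage I	lineage	l	Ilyodon whitei	Ilyodontini	L	Upper Balsas River	Balsas River Basin
Margotrema bravoae Lineage II	lineage	i	Characodon audax	Characodontini	B	Upper and Middle Mezquital River	Mezquital River Basin
Margotrema bravoae Lineage III	lineage	o	Zoogoneticus purhepechus	Chapalichthyini	C	Lower Lerma River	Lerma River Basin
Margotrema bravoae Lineage III	lineage	f	Allotoca zacapuensis	Girardinichthyini	D	Zacapu Lake	Lerma River Basin
Margotrema bravoae Lineage III	lineage	n	Zoogoneticus quitzeoensis	Chapalichthyini	D	Zacapu Lake	Lerma River Basin
Margotrema bravoae Lineage III	lineage	e	Alloophorus robustus	Chapalichthyini	E	Cuitzeo Lake	Lerma River Basin
Margotrema bravoae Lineage III	lineage	n	Zoogoneticus quitzeoensis	Chapalichthyini	E	Cuitzeo Lake	Lerma River Basin
Margotrema bravoae Lineage III	lineage	a	Allotoca diazi	Girardinichthyini	F	Pátzcuaro Lake	Lerma River Basin
Margotrema bravoae Lineage III	lineage	b	Allotoca duguesi	Girardinichthyini	F	Pátzcuaro Lake	Lerma River Basin
Margotrema bravoae Lineage III	lineage	c	Allotoca meeki	Girardinichthyini	G	Zirahuén Lake	Lerma River Basin
Margotrema bravoae Lineage III	lineage	d	Neoophorus regalis	Girardinichthyini	J	Cotija	Lerma River Basin
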