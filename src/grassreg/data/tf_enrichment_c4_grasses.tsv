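# Curated bundle-sheath vs mesophyll enrichment of grass orthologs of
# A. thaliana trans-acting factors (log2fc = log2(BS/M)).
# adj_p encodes the curation convention: 0.01 = reported significant in the
# source differential-expression analyses, 0.5 = reported not significant.
transcript_id	species_id	log2fc	adj_p	tf_id	tf_name
Pavir.8NG077400.2	Pvirgatum	3.6	0.5	AT3G18990	VRN1
Sevir.8G068300.1	Sviridis	1.4	0.01	AT3G18990	VRN1
Pahal.5G488600.2	Phallii	3.2	0.5	AT5G63090	LOB
Seita.5G119400.1	Sitalica	4.6	0.5	AT5G63090	LOB
Sevir.3G064900.1	Sviridis	6.4	0.01	AT3G55370	OBP3
Pahal.3G092800.1	Phallii	3.5	0.5	AT3G55370	OBP3
Seita.3G064100.1	Sitalica	5.4	0.01	AT3G55370	OBP3
Sevir.3G064900.2	Sviridis	6.6	0.01	AT3G55370	OBP3
Pahal.3G092800.2	Phallii	7.9	0.01	AT3G55370	OBP3
Seita.9G033400.1	Sitalica	5.8	0.01	AT3G55370	OBP3
Sevir.3G064900.3	Sviridis	4.9	0.01	AT3G55370	OBP3
Pahal.3G092800.3	Phallii	3.6	0.01	AT3G55370	OBP3
Seita.9G452000.1	Sitalica	7.2	0.01	AT3G55370	OBP3
Sevir.9G032600.1	Sviridis	6.5	0.01	AT3G55370	OBP3
Pahal.9G030900.1	Phallii	5.4	0.01	AT3G55370	OBP3
Sevir.9G455900.1	Sviridis	7.9	0.01	AT3G55370	OBP3
Pahal.9G513900.1	Phallii	3.1	0.01	AT3G55370	OBP3
Sevir.9G455900.2	Sviridis	7.0	0.01	AT3G55370	OBP3
Pahal.9G513900.2	Phallii	9.8	0.01	AT3G55370	OBP3
Sevir.3G015900.1	Sviridis	2.2	0.5	At5g66940	At5g66940
Pahal.7G338900.1	Phallii	2.8	0.5	At5g66940	At5g66940
Seita.3G014900.1	Sitalica	5.1	0.01	At5g66940	At5g66940
Pavir.5KG593700.1	Pvirgatum	3.3	0.01	AT3G56850	AREB3
Sevir.9G425100.2	Sviridis	5.1	0.01	AT3G56850	AREB3
Sevir.4G224600.1	Sviridis	-0.3	0.5	AT3G12130	AT3G12130
Pahal.1G071400.1	Phallii	-0.9	0.5	AT3G12130	AT3G12130
Seita.3G029300.2	Sitalica	-0.9	0.5	AT3G12130	AT3G12130
Sevir.4G224600.2	Sviridis	-1.7	0.5	AT3G12130	AT3G12130
Pahal.1G071400.3	Phallii	-7.3	0.5	AT3G12130	AT3G12130
Seita.4G214800.1	Sitalica	-0.5	0.5	AT3G12130	AT3G12130
Sevir.1G261900.1	Sviridis	-1.1	0.5	AT5G47230	ERF5
Pahal.9G383200.1	Phallii	-3.0	0.01	AT5G47230	ERF5
Seita.1G257600.1	Sitalica	-1.7	0.01	AT5G47230	ERF5
Sevir.3G246200.2	Sviridis	-5.4	0.5	AT1G65620	AS2
Seita.5G408700.1	Sitalica	-3.4	0.01	AT1G65620	AS2
Sevir.8G100900.1	Sviridis	-5.3	0.01	AT3G23240	ERF1
Pahal.2G139200.1	Phallii	-3.4	0.01	AT3G23240	ERF1
Seita.2G138400.1	Sitalica	-2.9	0.01	AT3G23240	ERF1
Sevir.9G504700.1	Sviridis	-3.7	0.01	AT3G23240	ERF1
Pahal.8G262800.1	Phallii	1.9	0.5	AT3G23240	ERF1
Seita.9G500100.1	Sitalica	-1.8	0.5	AT3G23240	ERF1
Pavir.5NG539500.1	Pvirgatum	-2.4	0.5	AT5G44210	ERF9
Sevir.3G196300.1	Sviridis	1.2	0.5	AT5G44210	ERF9
Seita.5G348000.1	Sitalica	-1.4	0.01	AT5G44210	ERF9
Sevir.5G352700.1	Sviridis	-2.5	0.01	AT5G44210	ERF9
Sevir.2G118100.1	Sviridis	-4.5	0.01	AT2G31230	ERF15
Pahal.8G107700.1	Phallii	-1.5	0.5	AT2G31230	ERF15
Seita.2G112200.1	Sitalica	-2.1	0.01	AT2G31230	ERF15
Sevir.8G182200.1	Sviridis	5.7	0.5	AT2G31230	ERF15
Seita.8G173100.1	Sitalica	7.6	0.01	AT2G31230	ERF15
Seita.8G237900.1	Sitalica	4.3	0.01	AT2G31230	ERF15
Sevir.2G055300.3	Sviridis	-6.2	0.5	AT4G14770	TCX2
Pahal.3G490800.1	Phallii	0.7	0.5	AT4G14770	TCX2
Seita.2G050700.1	Sitalica	-3.6	0.01	AT4G14770	TCX2
Sevir.3G398500.1	Sviridis	0.7	0.5	AT4G14770	TCX2
Pahal.9G158300.1	Phallii	7.0	0.01	AT4G14770	TCX2
Seita.3G382000.1	Sitalica	-0.7	0.5	AT4G14770	TCX2
Sevir.9G159400.4	Sviridis	5.0	0.01	AT4G14770	TCX2
Seita.9G161100.3	Sitalica	5.1	0.5	AT4G14770	TCX2
Sevir.9G159400.6	Sviridis	4.8	0.01	AT4G14770	TCX2
Seita.9G161100.2	Sitalica	7.5	0.5	AT4G14770	TCX2
Sevir.9G159400.1	Sviridis	2.7	0.5	AT4G14770	TCX2
Sevir.9G159400.7	Sviridis	4.1	0.01	AT4G14770	TCX2
Pavir.9NG798900.1	Pvirgatum	5.5	0.5	AT1G72360	ERF73
Sevir.2G400300.5	Sviridis	2.9	0.01	AT1G72360	ERF73
Pahal.2G447100.1	Phallii	1.8	0.01	AT1G72360	ERF73
Seita.2G390000.1	Sitalica	3.6	0.01	AT1G72360	ERF73
Sevir.9G520900.1	Sviridis	-1.4	0.01	AT1G72360	ERF73
Pahal.2G447100.2	Phallii	2.2	0.01	AT1G72360	ERF73
Seita.2G390000.3	Sitalica	1.2	0.01	AT1G72360	ERF73
Sevir.9G521200.2	Sviridis	-4.1	0.01	AT1G72360	ERF73
Pahal.9G580000.1	Phallii	-1.4	0.01	AT1G72360	ERF73
Seita.9G516500.1	Sitalica	-1.9	0.01	AT1G72360	ERF73
Pahal.9G580100.1	Phallii	-2.1	0.01	AT1G72360	ERF73
Seita.9G516600.1	Sitalica	3.0	0.5	AT1G72360	ERF73
Pahal.9G580200.1	Phallii	-2.1	0.01	AT1G72360	ERF73
Seita.9G516700.1	Sitalica	-4.2	0.01	AT1G72360	ERF73
Pahal.9G580200.2	Phallii	-2.1	0.01	AT1G72360	ERF73
Seita.9G516700.2	Sitalica	-4.1	0.01	AT1G72360	ERF73
Seita.9G516800.1	Sitalica	-3.6	0.01	AT1G72360	ERF73
Seita.9G516800.2	Sitalica	3.4	0.01	AT1G72360	ERF73
Sevir.2G084800.1	Sviridis	0.8	0.5	AT2G35530	bZIP16
Pahal.1G023000.4	Phallii	1.1	0.01	AT2G35530	bZIP16
Seita.3G090500.2	Sitalica	1.2	0.01	AT2G35530	bZIP16
Sevir.3G092500.1	Sviridis	-0.7	0.5	AT2G35530	bZIP16
Pahal.1G023000.5	Phallii	-0.7	0.5	AT2G35530	bZIP16
Seita.3G090500.3	Sitalica	-9.7	0.5	AT2G35530	bZIP16
Pahal.1G023000.6	Phallii	1.6	0.01	AT2G35530	bZIP16
Seita.9G474400.1	Sitalica	0.3	0.5	AT2G35530	bZIP16
Pahal.3G063900.2	Phallii	0.6	0.5	AT2G35530	bZIP16
Pahal.9G536900.1	Phallii	0.5	0.5	AT2G35530	bZIP16
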