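tf_id	species_id	transcript_id	tf_name
AT3G18990	Pvirgatum	Pavir.8NG077400.2	VRN1
AT3G18990	Sviridis	Sevir.8G068300.1	VRN1
AT5G63090	Phallii	Pahal.5G488600.2	LOB
AT5G63090	Sitalica	Seita.5G119400.1	LOB
AT3G55370	Sviridis	Sevir.3G064900.1	OBP3
AT3G55370	Phallii	Pahal.3G092800.1	OBP3
AT3G55370	Sitalica	Seita.3G064100.1	OBP3
AT3G55370	Sviridis	Sevir.3G064900.2	OBP3
AT3G55370	Phallii	Pahal.3G092800.2	OBP3
AT3G55370	Sitalica	Seita.9G033400.1	OBP3
AT3G55370	Sviridis	Sevir.3G064900.3	OBP3
AT3G55370	Phallii	Pahal.3G092800.3	OBP3
AT3G55370	Sitalica	Seita.9G452000.1	OBP3
AT3G55370	Sviridis	Sevir.9G032600.1	OBP3
AT3G55370	Phallii	Pahal.9G030900.1	OBP3
AT3G55370	Sviridis	Sevir.9G455900.1	OBP3
AT3G55370	Phallii	Pahal.9G513900.1	OBP3
AT3G55370	Sviridis	Sevir.9G455900.2	OBP3
AT3G55370	Phallii	Pahal.9G513900.2	OBP3
At5g66940	Sviridis	Sevir.3G015900.1	At5g66940
At5g66940	Phallii	Pahal.7G338900.1	At5g66940
At5g66940	Sitalica	Seita.3G014900.1	At5g66940
AT3G56850	Pvirgatum	Pavir.5KG593700.1	AREB3
AT3G56850	Sviridis	Sevir.9G425100.2	AREB3
AT3G12130	Sviridis	Sevir.4G224600.1	AT3G12130
AT3G12130	Phallii	Pahal.1G071400.1	AT3G12130
AT3G12130	Sitalica	Seita.3G029300.2	AT3G12130
AT3G12130	Sviridis	Sevir.4G224600.2	AT3G12130
AT3G12130	Phallii	Pahal.1G071400.3	AT3G12130
AT3G12130	Sitalica	Seita.4G214800.1	AT3G12130
AT5G47230	Sviridis	Sevir.1G261900.1	ERF5
AT5G47230	Phallii	Pahal.9G383200.1	ERF5
AT5G47230	Sitalica	Seita.1G257600.1	ERF5
AT1G65620	Sviridis	Sevir.3G246200.2	AS2
AT1G65620	Sitalica	Seita.5G408700.1	AS2
AT3G23240	Sviridis	Sevir.8G100900.1	ERF1
AT3G23240	Phallii	Pahal.2G139200.1	ERF1
AT3G23240	Sitalica	Seita.2G138400.1	ERF1
AT3G23240	Sviridis	Sevir.9G504700.1	ERF1
AT3G23240	Phallii	Pahal.8G262800.1	ERF1
AT3G23240	Sitalica	Seita.9G500100.1	ERF1
AT5G44210	Pvirgatum	Pavir.5NG539500.1	ERF9
AT5G44210	Sviridis	Sevir.3G196300.1	ERF9
AT5G44210	Sitalica	Seita.5G348000.1	ERF9
AT5G44210	Sviridis	Sevir.5G352700.1	ERF9
AT2G31230	Sviridis	Sevir.2G118100.1	ERF15
AT2G31230	Phallii	Pahal.8G107700.1	ERF15
AT2G31230	Sitalica	Seita.2G112200.1	ERF15
AT2G31230	Sviridis	Sevir.8G182200.1	ERF15
AT2G31230	Sitalica	Seita.8G173100.1	ERF15
AT2G31230	Sitalica	Seita.8G237900.1	ERF15
AT4G14770	Sviridis	Sevir.2G055300.3	TCX2
AT4G14770	Phallii	Pahal.3G490800.1	TCX2
AT4G14770	Sitalica	Seita.2G050700.1	TCX2
AT4G14770	Sviridis	Sevir.3G398500.1	TCX2
AT4G14770	Phallii	Pahal.9G158300.1	TCX2
AT4G14770	Sitalica	Seita.3G382000.1	TCX2
AT4G14770	Sviridis	Sevir.9G159400.4	TCX2
AT4G14770	Sitalica	Seita.9G161100.3	TCX2
AT4G14770	Sviridis	Sevir.9G159400.6	TCX2
AT4G14770	Sitalica	Seita.9G161100.2	TCX2
AT4G14770	Sviridis	Sevir.9G159400.1	TCX2
AT4G14770	Sviridis	Sevir.9G159400.7	TCX2
AT1G72360	Pvirgatum	Pavir.9NG798900.1	ERF73
AT1G72360	Sviridis	Sevir.2G400300.5	ERF73
AT1G72360	Phallii	Pahal.2G447100.1	ERF73
AT1G72360	Sitalica	Seita.2G390000.1	ERF73
AT1G72360	Sviridis	Sevir.9G520900.1	ERF73
AT1G72360	Phallii	Pahal.2G447100.2	ERF73
AT1G72360	Sitalica	Seita.2G390000.3	ERF73
AT1G72360	Sviridis	Sevir.9G521200.2	ERF73
AT1G72360	Phallii	Pahal.9G580000.1	ERF73
AT1G72360	Sitalica	Seita.9G516500.1	ERF73
AT1G72360	Phallii	Pahal.9G580100.1	ERF73
AT1G72360	Sitalica	Seita.9G516600.1	ERF73
AT1G72360	Phallii	Pahal.9G580200.1	ERF73
AT1G72360	Sitalica	Seita.9G516700.1	ERF73
AT1G72360	Phallii	Pahal.9G580200.2	ERF73
AT1G72360	Sitalica	Seita.9G516700.2	ERF73
AT1G72360	Sitalica	Seita.9G516800.1	ERF73
AT1G72360	Sitalica	Seita.9G516800.2	ERF73
AT2G35530	Sviridis	Sevir.2G084800.1	bZIP16
AT2G35530	Phallii	Pahal.1G023000.4	bZIP16
AT2G35530	Sitalica	Seita.3G090500.2	bZIP16
AT2G35530	Sviridis	Sevir.3G092500.1	bZIP16
AT2G35530	Phallii	Pahal.1G023000.5	bZIP16
AT2G35530	Sitalica	Seita.3G090500.3	bZIP16
AT2G35530	Phallii	Pahal.1G023000.6	bZIP16
AT2G35530	Sitalica	Seita.9G474400.1	bZIP16
AT2G35530	Phallii	Pahal.3G063900.2	bZIP16
AT2G35530	Phallii	Pahal.9G536900.1	bZIP16
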