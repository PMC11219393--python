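species	common_name	targeted_capture_depth	wga_depth
Mmul	rhesus macaque	1480	66
Mfus	Japanese macaque	1243	42
Mnig	Celebes crested macaque	1224	31
Panu	anubis baboon	1372	60
Pham	hamadryas baboon	1328	51
Epat	patas monkey	353	52
Csab	green monkey	1398	75
Cmit	blue monkey	1696	83
Cpol	king colobus	1436	NA
Sent	Hanuman langur	1333	29
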