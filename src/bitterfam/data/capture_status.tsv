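species	gene	status
Mmul	TAS2R418	absent
Mfus	TAS2R418	absent
Mnig	TAS2R418	absent
Panu	TAS2R418	intact
Pham	TAS2R418	intact
Epat	TAS2R418	intact
Csab	TAS2R418	absent
Cmit	TAS2R418	absent
Cpol	TAS2R418	absent
Sent	TAS2R418	absent
Mmul	TAS2R15	absent
Mfus	TAS2R15	absent
Mnig	TAS2R15	absent
Panu	TAS2R15	absent
Pham	TAS2R15	absent
Epat	TAS2R15	absent
Csab	TAS2R15	absent
Cmit	TAS2R15	absent
Cpol	TAS2R15	absent
Sent	TAS2R15	absent
Mmul	TAS2R64	disrupted
Mfus	TAS2R64	absent
Mnig	TAS2R64	absent
Panu	TAS2R64	absent
Pham	TAS2R64	absent
Epat	TAS2R64	absent
Csab	TAS2R64	absent
Cmit	TAS2R64	absent
Cpol	TAS2R64	absent
Sent	TAS2R64	absent
Mmul	TAS2R409	absent
Mfus	TAS2R409	absent
Mnig	TAS2R409	absent
Panu	TAS2R409	absent
Pham	TAS2R409	absent
Epat	TAS2R409	absent
Csab	TAS2R409	absent
Cmit	TAS2R409	absent
Cpol	TAS2R409	absent
Sent	TAS2R409	absent
Mmul	TAS2R62	absent
Mfus	TAS2R62	absent
Mnig	TAS2R62	absent
Panu	TAS2R62	absent
Pham	TAS2R62	absent
Epat	TAS2R62	absent
Csab	TAS2R62	absent
Cmit	TAS2R62	absent
Cpol	TAS2R62	absent
Sent	TAS2R62	absent
Mmul	TAS2R67	absent
Mfus	TAS2R67	absent
Mnig	TAS2R67	absent
Panu	TAS2R67	absent
Pham	TAS2R67	absent
Epat	TAS2R67	absent
Csab	TAS2R67	absent
Cmit	TAS2R67	absent
Cpol	TAS2R67	absent
Sent	TAS2R67	absent
Mmul	TAS2R404	absent
Mfus	TAS2R404	absent
Mnig	TAS2R404	absent
Panu	TAS2R404	absent
Pham	TAS2R404	absent
Epat	TAS2R404	absent
Csab	TAS2R404	absent
Cmit	TAS2R404	absent
Cpol	TAS2R404	absent
Sent	TAS2R404	absent
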