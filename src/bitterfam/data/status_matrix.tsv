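species	gene	status	category	group	shared_group	birth_source
Mmul	TAS2R410	intact		TAS2R405		inferred
Mfus	TAS2R410	intact		TAS2R405		inferred
Mnig	TAS2R410	intact		TAS2R405		inferred
Panu	TAS2R410	intact		TAS2R405		inferred
Pham	TAS2R410	intact		TAS2R405		inferred
Epat	TAS2R410	intact		TAS2R405		inferred
Csab	TAS2R410	intact		TAS2R405		inferred
Cmit	TAS2R410	intact		TAS2R405		inferred
Cpol	TAS2R410	intact		TAS2R405		inferred
Sent	TAS2R410	intact		TAS2R405		inferred
Mmul	TAS2R411	intact		TAS2R405		inferred
Mfus	TAS2R411	intact		TAS2R405		inferred
Mnig	TAS2R411	intact		TAS2R405		inferred
Panu	TAS2R411	intact		TAS2R405		inferred
Pham	TAS2R411	intact		TAS2R405		inferred
Epat	TAS2R411	intact		TAS2R405		inferred
Csab	TAS2R411	intact		TAS2R405		inferred
Cmit	TAS2R411	intact		TAS2R405		inferred
Cpol	TAS2R411	intact		TAS2R405		inferred
Sent	TAS2R411	intact		TAS2R405		inferred
Mmul	TAS2R412	intact		TAS2R405		inferred
Mfus	TAS2R412	intact		TAS2R405		inferred
Mnig	TAS2R412	intact		TAS2R405		inferred
Panu	TAS2R412	intact		TAS2R405		inferred
Pham	TAS2R412	intact		TAS2R405		inferred
Epat	TAS2R412	intact		TAS2R405		inferred
Csab	TAS2R412	intact		TAS2R405		inferred
Cmit	TAS2R412	intact		TAS2R405		inferred
Cpol	TAS2R412	intact		TAS2R405		inferred
Sent	TAS2R412	intact		TAS2R405		inferred
Mmul	TAS2R414	intact		TAS2R405		inferred
Mfus	TAS2R414	intact		TAS2R405		inferred
Mnig	TAS2R414	intact		TAS2R405		inferred
Panu	TAS2R414	intact		TAS2R405		inferred
Pham	TAS2R414	intact		TAS2R405		inferred
Epat	TAS2R414	intact		TAS2R405		inferred
Csab	TAS2R414	intact		TAS2R405		inferred
Cmit	TAS2R414	intact		TAS2R405		inferred
Cpol	TAS2R414	intact		TAS2R405		inferred
Sent	TAS2R414	intact		TAS2R405		inferred
Mmul	TAS2R415	intact		TAS2R405		inferred
Mfus	TAS2R415	intact		TAS2R405		inferred
Mnig	TAS2R415	intact		TAS2R405		inferred
Panu	TAS2R415	intact		TAS2R405		inferred
Pham	TAS2R415	intact		TAS2R405		inferred
Epat	TAS2R415	intact		TAS2R405		inferred
Csab	TAS2R415	intact		TAS2R405		inferred
Cmit	TAS2R415	intact		TAS2R405		inferred
Cpol	TAS2R415	intact		TAS2R405		inferred
Sent	TAS2R415	intact		TAS2R405		inferred
Mmul	TAS2R419	intact		TAS2R405		inferred
Mfus	TAS2R419	intact		TAS2R405		inferred
Mnig	TAS2R419	intact		TAS2R405		inferred
Panu	TAS2R419	intact		TAS2R405		inferred
Pham	TAS2R419	intact		TAS2R405		inferred
Epat	TAS2R419	intact		TAS2R405		inferred
Csab	TAS2R419	intact		TAS2R405		inferred
Cmit	TAS2R419	intact		TAS2R405		inferred
Cpol	TAS2R419	intact		TAS2R405		inferred
Sent	TAS2R419	intact		TAS2R405		inferred
Mmul	TAS2R413-1	intact	2	TAS2R405		inferred
Mfus	TAS2R413-1	intact	2	TAS2R405		inferred
Mnig	TAS2R413-1	intact	2	TAS2R405		inferred
Panu	TAS2R413-1	intact	2	TAS2R405		inferred
Pham	TAS2R413-1	intact	2	TAS2R405		inferred
Epat	TAS2R413-1	intact	2	TAS2R405		inferred
Csab	TAS2R413-1	intact	2	TAS2R405		inferred
Cmit	TAS2R413-1	intact	2	TAS2R405		inferred
Cpol	TAS2R413-1	intact	2	TAS2R405		inferred
Sent	TAS2R413-1	intact	2	TAS2R405		inferred
Mmul	TAS2R413-2	intact	2	TAS2R405		prior
Mfus	TAS2R413-2	intact	2	TAS2R405		prior
Mnig	TAS2R413-2	intact	2	TAS2R405		prior
Panu	TAS2R413-2	intact	2	TAS2R405		prior
Pham	TAS2R413-2	intact	2	TAS2R405		prior
Epat	TAS2R413-2	intact	2	TAS2R405		prior
Csab	TAS2R413-2	intact	2	TAS2R405		prior
Cmit	TAS2R413-2	intact	2	TAS2R405		prior
Cpol	TAS2R413-2	absent	2	TAS2R405		prior
Sent	TAS2R413-2	absent	2	TAS2R405		prior
Mmul	TAS2R418	absent		TAS2R405		prior
Mfus	TAS2R418	absent		TAS2R405		prior
Mnig	TAS2R418	absent		TAS2R405		prior
Panu	TAS2R418	intact		TAS2R405		prior
Pham	TAS2R418	intact		TAS2R405		prior
Epat	TAS2R418	intact		TAS2R405		prior
Csab	TAS2R418	absent		TAS2R405		prior
Cmit	TAS2R418	absent		TAS2R405		prior
Cpol	TAS2R418	absent		TAS2R405		prior
Sent	TAS2R418	absent		TAS2R405		prior
Mmul	TAS2R10-1	intact	2	TAS2R10		inferred
Mfus	TAS2R10-1	intact	2	TAS2R10		inferred
Mnig	TAS2R10-1	intact	2	TAS2R10		inferred
Panu	TAS2R10-1	intact	2	TAS2R10		inferred
Pham	TAS2R10-1	intact	2	TAS2R10		inferred
Epat	TAS2R10-1	intact	2	TAS2R10		inferred
Csab	TAS2R10-1	intact	2	TAS2R10		inferred
Cmit	TAS2R10-1	intact	2	TAS2R10		inferred
Cpol	TAS2R10-1	intact	2	TAS2R10		inferred
Sent	TAS2R10-1	intact	2	TAS2R10		inferred
Mmul	TAS2R10-2	intact	2	TAS2R10		prior
Mfus	TAS2R10-2	intact	2	TAS2R10		prior
Mnig	TAS2R10-2	intact	2	TAS2R10		prior
Panu	TAS2R10-2	intact	2	TAS2R10		prior
Pham	TAS2R10-2	intact	2	TAS2R10		prior
Epat	TAS2R10-2	intact	2	TAS2R10		prior
Csab	TAS2R10-2	intact	2	TAS2R10		prior
Cmit	TAS2R10-2	intact	2	TAS2R10		prior
Cpol	TAS2R10-2	absent	2	TAS2R10		prior
Sent	TAS2R10-2	absent	2	TAS2R10		prior
Mmul	TAS2R403	intact		TAS2R409		inferred
Mfus	TAS2R403	intact		TAS2R409		inferred
Mnig	TAS2R403	intact		TAS2R409		inferred
Panu	TAS2R403	intact		TAS2R409		inferred
Pham	TAS2R403	intact		TAS2R409		inferred
Epat	TAS2R403	intact		TAS2R409		inferred
Csab	TAS2R403	intact		TAS2R409		inferred
Cmit	TAS2R403	intact		TAS2R409		inferred
Cpol	TAS2R403	disrupted		TAS2R409	c403	inferred
Sent	TAS2R403	disrupted		TAS2R409	c403	inferred
Mmul	TAS2R404	absent		TAS2R409		prior
Mfus	TAS2R404	absent		TAS2R409		prior
Mnig	TAS2R404	absent		TAS2R409		prior
Panu	TAS2R404	absent		TAS2R409		prior
Pham	TAS2R404	absent		TAS2R409		prior
Epat	TAS2R404	absent		TAS2R409		prior
Csab	TAS2R404	absent		TAS2R409		prior
Cmit	TAS2R404	absent		TAS2R409		prior
Cpol	TAS2R404	absent		TAS2R409		prior
Sent	TAS2R404	absent		TAS2R409		prior
Mmul	TAS2R1	intact		TAS2R1		inferred
Mfus	TAS2R1	intact		TAS2R1		inferred
Mnig	TAS2R1	intact		TAS2R1		inferred
Panu	TAS2R1	intact		TAS2R1		inferred
Pham	TAS2R1	intact		TAS2R1		inferred
Epat	TAS2R1	intact		TAS2R1		inferred
Csab	TAS2R1	intact		TAS2R1		inferred
Cmit	TAS2R1	intact		TAS2R1		inferred
Cpol	TAS2R1	intact		TAS2R1		inferred
Sent	TAS2R1	intact		TAS2R1		inferred
Mmul	TAS2R3	intact		TAS2R3		inferred
Mfus	TAS2R3	intact		TAS2R3		inferred
Mnig	TAS2R3	intact		TAS2R3		inferred
Panu	TAS2R3	intact		TAS2R3		inferred
Pham	TAS2R3	intact		TAS2R3		inferred
Epat	TAS2R3	intact		TAS2R3		inferred
Csab	TAS2R3	intact		TAS2R3		inferred
Cmit	TAS2R3	intact		TAS2R3		inferred
Cpol	TAS2R3	intact		TAS2R3		inferred
Sent	TAS2R3	intact		TAS2R3		inferred
Mmul	TAS2R38	intact		TAS2R38		inferred
Mfus	TAS2R38	intact		TAS2R38		inferred
Mnig	TAS2R38	intact		TAS2R38		inferred
Panu	TAS2R38	intact		TAS2R38		inferred
Pham	TAS2R38	intact		TAS2R38		inferred
Epat	TAS2R38	intact		TAS2R38		inferred
Csab	TAS2R38	intact		TAS2R38		inferred
Cmit	TAS2R38	intact		TAS2R38		inferred
Cpol	TAS2R38	intact		TAS2R38		inferred
Sent	TAS2R38	intact		TAS2R38		inferred
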