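gene	Mmul_8.0.1	Mfas_5.0	Caty_1.0	Cang_1.0	Rrox_1.0
TAS2R1	intact	intact	disrupted	intact	intact
TAS2R2	truncated	intact	intact	truncated	intact
TAS2R3	truncated	intact	intact	intact	disrupted
TAS2R4	disrupted	intact	intact	intact	truncated
TAS2R5	disrupted	intact	truncated	intact	intact
TAS2R7	truncated	intact	truncated	truncated	disrupted
TAS2R8	intact	intact	intact	truncated	intact
TAS2R9	intact	disrupted	intact	truncated	intact
TAS2R10	truncated	intact	truncated	intact	intact
TAS2R13	truncated	truncated	intact	intact	intact
TAS2R14	truncated	intact	truncated	intact	truncated
TAS2R16	absent	absent	absent	intact	intact
TAS2R20	intact	disrupted	truncated	disrupted	intact
TAS2R38	disrupted	truncated	disrupted	intact	intact
TAS2R39	intact	intact	intact	intact	truncated
TAS2R40	intact	truncated	disrupted	intact	disrupted
TAS2R41	intact	truncated	intact	intact	truncated
TAS2R42	disrupted	disrupted	truncated	intact	disrupted
TAS2R46	disrupted	intact	intact	intact	disrupted
TAS2R50	intact	intact	intact	absent	disrupted
TAS2R60	disrupted	intact	intact	truncated	truncated
TAS2R403	intact	intact	intact	truncated	disrupted
TAS2R405	truncated	disrupted	intact	intact	intact
TAS2R410	disrupted	intact	intact	intact	truncated
TAS2R411	disrupted	intact	disrupted	intact	intact
TAS2R412	disrupted	intact	intact	truncated	intact
TAS2R413	disrupted	intact	intact	intact	intact
TAS2R414	intact	disrupted	disrupted	disrupted	intact
TAS2R415	intact	disrupted	disrupted	truncated	intact
TAS2R416	intact	disrupted	truncated	intact	disrupted
TAS2R417	intact	disrupted	intact	intact	intact
TAS2R418	disrupted	disrupted	disrupted	disrupted	disrupted
TAS2R15	disrupted	disrupted	disrupted	disrupted	disrupted
TAS2R64	disrupted	disrupted	disrupted	disrupted	disrupted
TAS2R409	disrupted	disrupted	disrupted	disrupted	disrupted
TAS2R62	absent	absent	absent	absent	absent
TAS2R67	absent	absent	absent	absent	absent
TAS2R404	absent	absent	absent	absent	absent
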