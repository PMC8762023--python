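cohort	variant	individual_id	group	kind	zygosity
1	T635C	S2	SLE	somatic
1	T635C	S7	SLE	somatic
1	T635C	S8	SLE	somatic
1	T635C	S16	SLE	somatic
1	T635C	S17	SLE	somatic
1	T635C	S29	SLE	somatic
1	T635C	S30	SLE	somatic
1	T635C	F10-4	SLE	somatic
1	T635C	F13-1	SLE	somatic
1	T635C	F14-1	SLE	somatic
1	T635C	F14-2	SLE	somatic
1	T635C	F15-1	SLE	somatic
1	T635C	F15-2	SLE	somatic
1	T635C	F18-1	SLE	somatic
1	T635C	F18-2	SLE	somatic
1	T635C	F19-3	SLE	somatic
1	T635C	F53-3	SLE	somatic
2	T635C	B14	SLE	somatic
2	T635C	B15	SLE	somatic
2	T635C	B16	SLE	somatic
2	T635C	B21	SLE	somatic
2	T635C	B22	SLE	somatic
2	T635C	B23	SLE	somatic
2	T635C	B24	SLE	somatic
2	T635C	B26	SLE	somatic
2	T635C	B29	SLE	somatic
2	T635C	B30	SLE	somatic
2	T635C	B31	SLE	somatic
2	T635C	B32	SLE	somatic
2	T635C	B37	SLE	somatic
2	T635C	B38	SLE	somatic
2	T635C	B39	SLE	somatic
2	T635C	B40	SLE	somatic
2	T635C	B41	SLE	somatic
2	T635C	B42	SLE	somatic
2	T635C	B47	SLE	somatic
2	T635C	B48	SLE	somatic
2	T635C	B53	SLE	somatic
2	T635C	B54	SLE	somatic
2	T635C	B55	SLE	somatic
2	T635C	B58	SLE	somatic
2	T635C	B61	SLE	somatic
2	T635C	B63	SLE	somatic
2	T635C	B64	SLE	somatic
2	T635C	B65	SLE	somatic
2	T635C	B67	SLE	somatic
2	T635C	B69	SLE	somatic
2	T635C	B70	SLE	somatic
2	T635C	B71	SLE	somatic
2	T635C	B73	SLE	somatic
2	T635C	B75	SLE	somatic
2	T635C	B76	SLE	somatic
2	T635C	B77	SLE	somatic
2	T635C	B79	SLE	somatic
1	A644C	F52-01	SLE	germline	het
1	A644C	F52-02	family_non_SLE	germline	het
2	A644C	B24	SLE	germline	het
2	A644C	B71	SLE	germline	het
1	A410T	S10	SLE	germline	het
1	A410T	F7-01	SLE	germline	het
1	A410T	F7-04	SLE	germline	het
2	A410T	B33	SLE	germline	het
2	A410T	B45	SLE	germline	het
1	K650R	F26-01	SLE	germline	het
1	K650R	F26-02	SLE	germline	het
2	A579T	B19	SLE	germline	het
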