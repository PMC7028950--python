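cluster	gene	ensembl_id	chrom	start	end	cattle_ensembl_id	cattle_chrom	cattle_start	cattle_end
1	ALB	ENSOARG00000013782	6	88136611	88159187	ENSBTAG00000017121	6	90232762	90251126
1	GC	ENSOARG00000012835	6	86619919	86657661	ENSBTAG00000013718	6	88695940	88739180
1	AFP	ENSOARG00000013966	6	88166794	88190190	ENSBTAG00000017131	6	90258976	90280522
1	AFM	ENSOARG00000014129	6	88198267	88224250	ENSBTAG00000047833	6	90291078	90312046
2	MC2R	ENSOARG00000003950	23	43893855	43894748	ENSBTAG00000011038	24	44006264	44024553
2	CIB1	ENSOARG00000012128	18	20723490	20727112	ENSBTAG00000021275	21	22043354	22046525
2	MC5R	ENSOARG00000002239	23	43867867	43870160	ENSBTAG00000009143	24	43983880	43984857
2	CAV1	ENSOARG00000001337	4	51786039	51820791	ENSBTAG00000017869	4	52173110	52208687
3	LDLRAD4	ENSOARG00000002144	23	43646788	43801055	ENSBTAG00000009139	24	43861727	43919241
3	LRP11	ENSOARG00000002898	8	73814860	73836141	ENSBTAG00000032007	9	88115145	88183314
3	CFI	ENSOARG00000005291	6	15708801	15753015	ENSBTAG00000034501	6	16765034	16815352
3	VLDLR	ENSOARG00000013303	2	70468444	70486178	ENSBTAG00000018517	8	42109679	42141155
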