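gene_symbol	subfamily	locus	position	tss	orientation	p_value
ECE1	AluSx1	chr1:21218585-21218890	3'UTR	no	Sense	4e-12
S100A9	AluSp	chr1:153359680-153359988	Intron	no	Inverted	3e-33
FCGR2A	AluSz6	chr1:161518618-161518922	3'UTR	yes ^1	Inverted	2e-23
SRGN	AluSz	chr10:69091596-69091908	Intron	no	Sense	9e-16
CD82	AluY	chr11:44619480-44619789	3'UTR	yes	Sense	3e-13
C1RL	AluSc	chr12:7095120-7095413	3'UTR	no	Sense	1e-21
C1RL	AluSq	chr12:7097283-7097581	Intron	no	Sense	1e-14
C1RL	AluSq2	chr12:7098913-7099254	Intron	yes ^1	Inverted	6e-20
RAB27A	AluY	chr15:55203412-55203721	3'UTR	no	Sense	1e-13
IGSF6	AluSx	chr16:21639920-21640237	3'UTR	no	Sense	9e-8
IGSF6	AluSx	chr16:21640468-21640796	3'UTR	yes	Inverted	2e-10
CXCL16	AluSx3	chr17:4733927-4734234	3'UTR	yes	Inverted	2e-12
COLGALT1	AluSz	chr19:17581909-17582208	3'UTR	yes	Inverted	2e-11
JAK3	AluY	chr19:17825619-17825921	3'UTR	yes	Inverted	1e-21
JAK3	AluSz	chr19:17826103-17826414	3'UTR	yes	Inverted	1e-17
JAK3	AluSx	chr19:17836278-17836571	Intron	no	Sense	3e-24
RASGRP4	AluSg	chr19:38409458-38409752	3'UTR	no	Inverted	4e-17
C5AR1	AluSx1	chr19:47321326-47321636	3'UTR	yes	Sense	2e-5
SIGLEC9	AluY	chr19:51131305-51131590	Intron	no	Sense	2e-16
SIGLEC9	AluSz	chr19:51131634-51131933	Intron	no	Sense	2e-15
SIGLEC9	AluSx1	chr19:51133290-51133609	Intron	no	Sense	7e-19
SIGLEC9	AluSc	chr19:51134129-51134456	Intron	no	Inverted	4e-20
SIGLEC14	AluSx1	chr19:51642741-51643045	3'UTR	yes	Inverted	4e-4
FPR1	AluSx1	chr19:51745155-51745455	3'UTR	no	Sense	3e-20
LILRB3	AluJb	chr19:54215999-54216282	3'UTR	no	Sense	1e-21
LILRB3	AluY	chr19:54216298-54216609	3'UTR	no	Sense	2e-21
LILRB3	AluJo	chr19:54216689-54216866	3'UTR	no	Sense	1e-20
LILRA6	AluSx3	chr19:54238010-54238335	Intron	no	Sense	3e-19
LILRA5	AluSc	chr19:54307138-54307296	3'UTR	no	Inverted	1e-26
FCAR	AluSx	chr19:54889964-54890253	3'UTR	no	Inverted	4e-23
FCAR	AluSg	chr19:54890415-54890727	3'UTR	yes	Inverted	6e-26
SLC11A1	AluSz	chr2:218383482-218383779	Intron	no	Inverted	3e-13
SLC11A1	AluSx1	chr2:218385379-218385690	Intron	no	Inverted	2e-8
SLC11A1	AluSc	chr2:218388087-218388396	Intron	yes	Sense	3e-13
SLC11A1	AluSx3	chr2:218388511-218388823	Intron	no	Sense	7e-20
SLC11A1	AluJb	chr2:218388830-218389102	Intron	no	Sense	6e-19
SLC11A1	AluJo	chr2:218389289-218389568	Intron	no	Sense	5e-14
SLC11A1	AluJo	chr2:218390899-218391030	Intron	no	Sense	4e-14
SLC11A1	AluSx1	chr2:218391611-218391922	Intron	yes	Inverted	4e-11
SLC11A1	AluSg	chr2:218391923-218392055	Intron	yes	Inverted	2e-11
SLC11A1	AluSp	chr2:218392056-218392362	Intron	yes	Inverted	3e-12
SLC11A1	AluJo	chr2:218392363-218392634	Intron	yes	Inverted	4e-13
SLC11A1	AluSz6	chr2:218395463-218395753	3'UTR	yes	Inverted	2e-17
IL10RB	AluSz	chr21:33296666-33296973	3'UTR	no	Sense	8e-25
NFKBIZ	AluJo	chr3:101860180-101860475	3'UTR	yes ^1	Inverted	2e-12
TNFSF10	AluSc	chr3:172505725-172506023	3'UTR	yes	Sense	1e-14
RNF144B	AluJo	chr6:18467641-18467939	3'UTR	yes	Inverted	3e-16
SERPINB1	AluSx	chr6:2832525-2832836	3'UTR	yes	Inverted	2e-21
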