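# Target-peptide panel for the PRM validation phase: 56 tryptic peptides covering 31 proteins,
# each with the reported response-curve linear range (fmol spiked on column; 10 pmol = 10000 fmol).
gene_symbol	peptide	linear_low_fmol	linear_high_fmol
APOB	WNFYYSPQSSPDK	0.01	10000
CAMK2A	FYFENLWSR	0.01	10000
CAMK2A	ITQYLDAGGIPR	0.01	10000
CAMK2A	VTEQLIEAISNGDFESYTK	0.01	10000
CHIT1	DNQWVGFDDVESFK	0.01	10000
IGLV3-19	ITCQGDSLR	0.1	10000
JCHAIN	FVYHLSDLCK	0.1	10000
LTA4H	WEDAIPLALK	0.1	10000
NFASC	LTVSWLK	0.1	10000
PPBP	ICLDPDAPR	0.1	10000
UCHL1	FSAVALCK	0.1	10000
CHIT1	YPLIQTLR	0.1	10000
ERAP2	ILAVTDFEPTQAR	0.1	10000
FSTL4	FDDYNSDSSLTLR	0.1	10000
APP	THPHFVIPYR	0.1	10000
APP	VESLEQEAANER	0.1	10000
APP	WYFDVTEGK	0.1	10000
CHI3L1	ILGQQVPYATK	0.1	10000
CNTNAP2	FSFSTTK	0.1	10000
MEGF8	LFPLPGR	0.1	10000
MFAP4	GFYYSLK	0.1	10000
NELL2	SALAYVDGK	0.1	10000
NPTX2	AAVLQLR	0.1	10000
NPTX2	TESTLNALLQR	0.1	10000
RTN4RL2	LFLQNNLIR	0.1	10000
SERPINA3	LINDYVK	0.1	10000
CHI3L1	QLLLSAALSAGK	0.1	10000
NPTX1	LENLEQYSR	0.1	10000
NPTX1	LPFVINDGK	0.1	10000
RTN4RL2	SLEPDTFQGLER	0.1	10000
SERPINA1	LSSWVLLMK	0.1	10000
SERPINA1	SVLGQLGITK	0.1	10000
TPI1	QSLGELIGTLNAAK	0.1	10000
MFAP4	ADGEYWLGLQNMHLLTLK	0.1	10000
GPNMB	AYVPIAQVK	1	10000
JCHAIN	IVLVDNK	1	10000
L1CAM	YDIEFEDK	1	10000
ST8SIA5	EINSADFVFR	1	10000
APOB	LPYTIITTPPLK	1	10000
CHI3L1	FPLTNAIK	1	10000
CLSTN1	YISNEFK	1	10000
CSPG5	EAGSAVEAEELVK	1	10000
LINGO1	HLNINAIR	1	10000
MEGF8	HVWTTLK	1	10000
NCAN	ELGGEVFYVGPAR	1	10000
NCAN	LSSAIIAAPR	1	10000
NCAN	QDLPILVAK	1	10000
NELL2	AFLFQDTPR	1	10000
NELL2	ASTATAEQFFQK	1	10000
NELL2	FTGSSWIK	1	10000
CHIT1	SSFYSCAAGR	10	10000
CHIT1	FTDMVATANNR	10	10000
CLSTN3	FTVTAYDCGK	10	10000
FSTL4	LLVESLFR	10	10000
SERPINA3	AVLDVFEEGTEASAATAVK	100	10000
SERPINA1	LYHSEAFTVNFGDTEEAK	100	10000
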