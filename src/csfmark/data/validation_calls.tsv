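# Peptides called significantly different (p < 0.05, unpaired two-tailed t-test) between ALS
# and HC in the PRM validation phase: 18 upregulated + 11 downregulated = 29 calls.
# For JCHAIN and FSTL4 the report states that one of the two quantified peptides was
# significant without naming it; the first-listed panel peptide is recorded here with
# peptide_ambiguous=True.
gene_symbol	peptide	direction	peptide_ambiguous
APOB	LPYTIITTPPLK	up	False
APOB	WNFYYSPQSSPDK	up	False
CHI3L1	ILGQQVPYATK	up	False
CHI3L1	QLLLSAALSAGK	up	False
CHI3L1	FPLTNAIK	up	False
CHIT1	DNQWVGFDDVESFK	up	False
CHIT1	YPLIQTLR	up	False
CHIT1	SSFYSCAAGR	up	False
CHIT1	FTDMVATANNR	up	False
GPNMB	AYVPIAQVK	up	False
ERAP2	ILAVTDFEPTQAR	up	False
JCHAIN	FVYHLSDLCK	up	True
SERPINA1	LSSWVLLMK	up	False
SERPINA1	SVLGQLGITK	up	False
SERPINA1	LYHSEAFTVNFGDTEEAK	up	False
SERPINA3	LINDYVK	up	False
SERPINA3	AVLDVFEEGTEASAATAVK	up	False
UCHL1	FSAVALCK	up	False
APP	THPHFVIPYR	down	False
APP	VESLEQEAANER	down	False
APP	WYFDVTEGK	down	False
CAMK2A	FYFENLWSR	down	False
CAMK2A	ITQYLDAGGIPR	down	False
CAMK2A	VTEQLIEAISNGDFESYTK	down	False
CLSTN3	FTVTAYDCGK	down	False
FSTL4	FDDYNSDSSLTLR	down	True
L1CAM	YDIEFEDK	down	False
NPTX2	AAVLQLR	down	False
NPTX2	TESTLNALLQR	down	False
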