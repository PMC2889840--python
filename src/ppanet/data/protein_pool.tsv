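TNF	IL-1	MyD88-dependent TLR-4	MyD88-independent TLR-4	Negative regulators
TNF	IL1α	MyD88	TLR4	A20
TNFR1	IL1β	TIRAP	TRAM	CYLD
TNFR2	IL1R1	CD14	TRIF	FLN29
TRADD	IL1R2	PELI2	TRAF3	IRAK3
FADD	TOLLIP	IRAK4	TANK	NOD2
GRB2	ST2L	IRAK1	TBK1	RIP3
SOS1	PELI1	NIK	IKKε	PTPN11
CAV1	ECSIT	BCL10	IRF3	RNF216
CASP8				SARM
TRAF2				SIGIRR
TRAF5				SOCS1
TTRAP				TMED1
TRAF6				TNIP3
RIP				TRAF4
MEKK3				UBE2N
TAK1
TAB1
TAB2
IKKα
IKKβ
IKKγ
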