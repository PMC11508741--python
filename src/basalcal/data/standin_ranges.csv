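species_id,c_min_nM,c_max_nM,monitored,source_note
AC,50.0,150.0,1,
AKTA,50.0,150.0,1,
AMPK,50.0,500.00000000000006,1,
ATG5,0.0,20.0,1,
ATG5T,0.0,100.0,1,
BCL2,50.0,150.0,1,
BCL2_BAX,0.0,70.0,1,
BCL2_PUMA,0.0,100.0,1,
BEC1,50.0,150.0,1,
BAX,0.0,60.0,1,
BID,0.0,10.0,1,
CA2ER,500.00000000000006,2000.0000000000002,1,
CA2IC,0.0,300.0,1,
CAMKKB,50.0,500.00000000000006,1,
CALPAIN,0.0,100.0,1,
DAPK,0.0,100.0,1,
EPAC,50.0,150.0,1,
GPCRA,0.0,100.0,1,
GA,0.0,100.0,1,
GBC,0.0,100.0,1,
IP3,0.0,100.0,1,
PIP2,100.0,1000.0000000000001,1,
PKA,50.0,500.00000000000006,1,
PKC,50.0,500.00000000000006,1,
PLCE,0.0,100.0,1,
RHEBA,40.0,60.0,1,
SERCA,400.0,600.0,1,
TSC,0.0,100.0,1,
ULK,50.0,150.0,1,
UVG,0.0,100.0,1,
CYTCM,100.0,1000.0000000000001,1,
MTORA,50.0,150.0,1,
P53,0.0,100.0,1,
PROCASP,100.0,1000.0000000000001,1,
MTOR,100.0,300.0,0,
AKT,50.0,150.0,0,
EPACA,0.0,100.0,0,
PUMA,0.0,50.0,0,
P53A,0.0,60.0,0,
CAMKKBA,0.0,100.0,0,
AMPKA,0.0,100.0,0,
ATG5_BCL2,0.0,50.0,0,
PKC_CA2IC,0.0,50.0,0,
P53A_BCL2,0.0,50.0,0,
GPCR,0.0,100.0,0,
PLCEA,0.0,100.0,0,
RHEB,0.0,100.0,0,
TSCA,0.0,100.0,0,
ULKA,0.0,100.0,0,
DAPKA,0.0,100.0,0,
CALPAINA,0.0,100.0,0,
UVGA,0.0,100.0,0,
CASP,0.0,10.0,0,
CYTC,0.0,100.0,0,
ACA,0.0,100.0,0,
CAMP,0.0,100.0,0,
IP3R,0.0,100.0,0,
MDM2,0.0,100.0,0,
BNIP3,0.0,100.0,0,
HMGB1,0.0,100.0,0,
ATG7,0.0,100.0,0,
ATG12,0.0,100.0,0,
LC3,0.0,100.0,0,
LC3II,0.0,100.0,0,
P62,0.0,100.0,0,
LAMP2,0.0,100.0,0,
RAB7,0.0,100.0,0,
VPS34,0.0,100.0,0,
PP2A,0.0,100.0,0,
ATF4,0.0,100.0,0,
BCL2_BEC1,0.0,100.0,0,
IP3R_IP3,0.0,50.0,0,
VPS34_BEC1,0.0,50.0,0,
ATG12_ATG7,0.0,50.0,0,
LC3II_UVG,0.0,50.0,0,
MDM2_P53,0.0,50.0,0,
PKAA,0.0,50.0,0,
RAB7_UVG,0.0,50.0,0,
GA_AC,0.0,50.0,0,
ERSTRESS,0.0,0.0,0,
DNADMG,0.0,0.0,0,
STARV,0.0,0.0,0,
TBID,0.0,0.0,0,
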