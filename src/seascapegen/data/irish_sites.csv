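site_code,location,region,latitude,longitude,n,stock_type,habitat
MB,Mulroy Bay,North,55.15488,-7.68000,30,Farm,Subtidal
LF,Lough Foyle,North,55.09047,-7.08548,30,Farm,Subtidal
CB,Clew Bay,West,53.86222,-9.62820,29,Farm,Subtidal
KF,Killary Fjord,West,53.60487,-9.80624,29,Farm,Subtidal
SCBB,Bertraghboy Bay,West,53.39689,-9.82947,22,Wild,Intertidal
AI,Aran Islands,West,53.08083,-9.57142,30,Wild,Intertidal
CRW,Cromane Wild,Southwest,52.09275,-9.96550,30,Wild,Subtidal
CRF,Cromane Farm,Southwest,52.13825,-9.93817,30,Farm,Intertidal
SBB,Snave Bantry Bay,Southwest,51.71223,-9.47268,30,Farm,Subtidal
RWB,Roaringwater Bay,South,51.53507,-9.41850,28,Farm,Subtidal
CKH,Cork Harbour,South,51.88000,-8.25000,30,Wild,Intertidal
WF,Waterford Estuary,South,52.24000,-6.97000,30,Wild,Intertidal
KLM,Kilmakilloge,South,51.77100,-9.82938,30,Farm,Subtidal
DH,Dungarvan Harbour,South,52.10006,-7.58435,29,Wild,Intertidal
RSW,Rosslare,East,52.25820,-6.31087,30,Wild,Subtidal
WX,Wexford Harbour,East,52.33273,-6.43135,30,Farm,Subtidal
AWWF,Arklow Wind Farm,East,52.78000,-5.95231,30,Wild,Intertidal
WK,Wicklow,East,52.93878,-5.93775,30,Wild,Subtidal
DLM,Dun Laoghaire Marina,East,53.29000,-6.14000,30,Wild,Intertidal
NBW,North Bull Wall,East,53.35000,-6.16000,30,Wild,Intertidal
MH,Malahide,East,53.45000,-6.13000,30,Wild,Intertidal
RT,Rogerstown,East,53.51256,-6.13003,30,Wild,Intertidal
DP,Dunany Point,East,53.86600,-6.24622,30,Wild,Intertidal
CL,Carlingford Lough,East,54.07942,-6.23708,30,Farm,Subtidal
NI12,Dunseverick,North,55.23881,-6.43339,35,Wild,Intertidal
NI13,Bangor,North,54.67210,-5.63544,39,Wild,Intertidal
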