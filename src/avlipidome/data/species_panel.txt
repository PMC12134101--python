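CE 18:2
CE 18:1
CE 16:0
CE 18:3
CE 20:4
CE 16:1
CE 18:0
CE 20:3
CE 20:5
CE 22:4
CE 22:6
CE 14:0
TG 44:0
TG 44:1
TG 44:2
TG 44:3
TG 44:4
TG 44:5
TG 44:6
TG 44:7
TG 44:8
TG 46:0
TG 46:1
TG 46:2
TG 46:3
TG 46:4
TG 46:5
TG 46:6
TG 46:7
TG 46:8
TG 48:0
TG 48:1
TG 48:2
TG 48:3
TG 48:4
TG 48:5
TG 48:6
TG 48:7
TG 48:8
TG 50:0
TG 50:1
TG 50:2
TG 50:3
TG 50:4
TG 50:5
TG 50:6
TG 50:7
TG 50:8
TG 52:0
TG 52:1
TG 52:2
TG 52:3
TG 52:4
TG 52:5
TG 52:6
TG 52:7
TG 52:8
TG 54:0
TG 54:1
TG 54:2
TG 54:3
TG 54:4
TG 54:5
TG 54:6
TG 54:7
TG 54:8
TG 56:0
TG 56:1
TG 56:2
TG 56:3
TG 56:4
TG 56:5
TG 56:6
TG 56:7
TG 56:8
TG 58:0
TG 58:1
TG 58:2
TG 58:3
TG 58:4
TG 58:5
TG 58:6
TG 58:7
TG 58:8
TG 60:0
TG 60:1
TG 60:2
TG 60:3
TG 60:4
TG 60:5
TG 60:6
TG 60:7
TG 60:8
TG 62:0
TG 62:1
TG 62:2
TG 62:3
TG 62:4
TG 62:5
TG 62:6
TG 62:7
TG 62:8
DG 30:0
DG 30:1
DG 30:2
DG 30:3
DG 30:4
DG 32:0
DG 32:1
DG 32:2
DG 32:3
DG 32:4
DG 34:0
DG 34:1
DG 34:2
DG 34:3
DG 34:4
DG 36:0
DG 36:1
DG 36:2
DG 36:3
DG 36:4
DG 38:0
DG 38:1
DG 38:2
DG 38:3
DG 38:4
MG 16:0
MG 18:0
MG 18:1
FA 14:0
FA 16:0
FA 16:1
FA 18:0
FA 18:1
FA 18:2
FA 20:4
FA 20:5
FA 22:5
FA 22:6
ST 27:1;O
PC 30:0
PC 30:1
PC 30:2
PC 30:3
PC 30:4
PC 30:5
PC 31:0
PC 31:1
PC 31:2
PC 31:3
PC 31:4
PC 31:5
PC 32:0
PC 32:1
PC 32:2
PC 32:3
PC 32:4
PC 32:5
PC 33:0
PC 33:1
PC 33:2
PC 33:3
PC 33:4
PC 33:5
PC 34:0
PC 34:1
PC 34:2
PC 34:3
PC 34:4
PC 34:5
PC 35:0
PC 35:1
PC 35:2
PC 35:3
PC 35:4
PC 35:5
PC 36:0
PC 36:1
PC 36:2
PC 36:3
PC 36:4
PC 36:5
PC 37:0
PC 37:1
PC 37:2
PC 37:3
PC 37:4
PC 37:5
PC 38:0
PC 38:1
PC 38:2
PC 38:3
PC 38:4
PC 38:5
PC 39:0
PC 39:1
PC 39:2
PC 39:3
PC 39:4
PC 39:5
PE 34:1
PE 34:2
PE 34:3
PE 34:4
PE 34:5
PE 35:1
PE 35:2
PE 35:3
PE 35:4
PE 35:5
PE 36:1
PE 36:2
PE 36:3
PE 36:4
PE 36:5
PE 37:1
PE 37:2
PE 37:3
PE 37:4
PE 37:5
PE 38:1
PE 38:2
PE 38:3
PE 38:4
PE 38:5
PE 39:1
PE 39:2
PE 39:3
PE 39:4
PE 39:5
PE 40:1
PE 40:2
PE 40:3
PE 40:4
PE 40:5
PE P-34:2
PE P-34:3
PE P-34:4
PE P-34:5
PE P-34:6
PE P-35:2
PE P-35:3
PE P-35:4
PE P-35:5
PE P-35:6
PE P-36:2
PE P-36:3
PE P-36:4
PE P-36:5
PE P-36:6
PE P-37:2
PE P-37:3
PE P-37:4
PE P-37:5
PE P-37:6
PE P-38:2
PE P-38:3
PE P-38:4
PE P-38:5
PE P-38:6
PE P-39:2
PE P-39:3
PE P-39:4
PE P-39:5
PE P-39:6
PE P-40:2
PE P-40:3
PE P-40:4
PE P-40:5
PE P-40:6
PS 34:1
PS 34:2
PS 34:3
PS 34:4
PS 34:5
PS 35:1
PS 35:2
PS 35:3
PS 35:4
PS 35:5
PS 36:1
PI 34:1
PI 34:2
PI 34:3
PI 35:1
PI 35:2
PI 35:3
PI 36:1
PI 36:2
PI 36:3
PI 37:1
PI 37:2
PI 37:3
PI 38:1
PI 38:2
PI 38:3
PG 32:1
PG 32:2
PG 34:1
PG 34:2
PG 36:1
PG 36:2
PG 38:1
PG 38:2
PA 34:1
CL 68:5
CL 70:6
CL 70:7
CL 72:7
CL 72:8
LPC 14:0
LPC 14:1
LPC 15:0
LPC 15:1
LPC 16:0
LPC 16:1
LPC 17:0
LPC 17:1
LPC 18:0
LPC 18:1
LPC 19:0
LPC 19:1
LPC 20:0
LPC 20:1
LPC 21:0
LPE 16:0
LPE 16:1
LPE 17:0
LPE 17:1
LPE 18:0
LPE 18:1
LPE 19:0
LPE 19:1
LPE 20:0
LPE 20:1
LPA 16:0
LPA 18:0
LPA 18:1
LPA 20:4
LPI 16:0
LPI 18:0
LPI 18:1
LPI 20:4
LPS 16:0
LPS 18:0
LPS 18:1
SM 18:1;O2/14:0
SM 18:1;O2/16:0
SM 18:1;O2/16:1
SM 18:1;O2/18:0
SM 18:1;O2/18:1
SM 18:1;O2/20:0
SM 18:1;O2/22:0
SM 18:1;O2/22:1
SM 18:1;O2/23:0
SM 18:1;O2/24:0
SM 18:1;O2/24:1
SM 18:1;O2/24:2
SM 18:1;O2/26:0
SM 18:1;O2/26:1
SM 18:0;O2/16:0
SM 18:0;O2/18:0
SM 18:0;O2/20:0
SM 18:0;O2/22:0
SM 18:0;O2/22:1
SM 18:0;O2/23:0
SM 18:0;O2/24:0
SM 18:0;O2/24:1
SM 18:0;O2/25:0
SM 18:0;O2/26:0
SM 16:1;O2/16:0
SM 16:1;O2/18:0
SM 16:1;O2/20:0
SM 16:1;O2/22:0
SM 16:1;O2/23:0
SM 16:1;O2/24:0
SM 16:1;O2/24:1
SM 16:1;O2/26:0
SM 18:1;O3/14:0
SM 18:1;O3/16:0
SM 18:1;O3/18:0
SM 18:1;O3/20:0
SM 18:1;O3/22:0
SM 18:1;O3/24:0
SM 18:1;O3/24:1
SM 18:1;O3/26:0
Cer 18:1;O2/24:0
Cer 18:1;O2/24:1
Cer 18:1;O2/16:0
Cer 18:1;O2/22:0
Cer 18:1;O2/23:0
Cer 18:1;O2/18:0
Cer 18:1;O2/22:1
Cer 18:1;O2/25:0
Cer 18:1;O2/26:0
Cer 18:1;O2/24:2
Cer 18:1;O2/20:0
Cer 18:1;O2/26:1
Cer 18:1;O2/14:0
Cer 16:1;O2/24:0
Cer 16:1;O2/24:1
Cer 16:1;O2/16:0
Cer 16:1;O2/22:0
Cer 16:1;O2/23:0
Cer 16:1;O2/26:0
Cer 17:1;O2/24:0
Cer 17:1;O2/24:1
Cer 17:1;O2/16:0
Cer 17:1;O2/22:0
Cer 17:1;O2/23:0
Cer 17:1;O2/26:0
Cer 19:1;O2/24:0
Cer 19:1;O2/24:1
Cer 19:1;O2/16:0
Cer 19:1;O2/22:0
Cer 19:1;O2/26:0
Cer 20:1;O2/24:0
Cer 20:1;O2/24:1
Cer 20:1;O2/16:0
Cer 20:1;O2/22:0
Cer 20:1;O2/26:0
Cer 18:0;O2/24:0
Cer 18:0;O2/24:1
Cer 18:0;O2/16:0
Cer 18:0;O2/22:0
Cer 18:0;O2/23:0
Cer 18:0;O2/18:0
Cer 18:0;O2/22:1
Cer 18:0;O2/25:0
Cer 18:0;O2/26:0
Cer 18:0;O2/24:2
Cer 18:0;O2/20:0
Cer 18:0;O2/26:1
Cer 18:1;O/24:0
Cer 18:1;O/24:1
Cer 18:1;O/16:0
Cer 18:1;O/22:0
Cer 18:1;O/23:0
Cer 18:1;O/18:0
Cer 18:1;O/25:0
Cer 18:1;O/26:0
Cer 18:0;O3/24:0
Cer 18:0;O3/24:1
Cer 18:0;O3/16:0
Cer 18:0;O3/22:0
Cer 18:0;O3/23:0
Cer 18:0;O3/18:0
Cer 18:0;O3/20:0
Cer 18:0;O3/25:0
Cer 18:0;O3/26:0
Cer 18:0;O3/26:1
Cer 18:2;O2/24:0
Cer 18:2;O2/24:1
Cer 18:2;O2/16:0
Cer 18:2;O2/22:0
Cer 18:2;O2/23:0
Cer 18:2;O2/18:0
Cer 18:2;O2/25:0
Cer 18:2;O2/26:0
HexCer 18:1;O2/14:0
HexCer 18:1;O2/16:0
HexCer 18:1;O2/18:0
HexCer 18:1;O2/20:0
HexCer 18:1;O2/22:0
HexCer 18:1;O2/23:0
HexCer 18:1;O2/24:0
HexCer 18:1;O2/24:1
HexCer 18:1;O2/24:2
HexCer 18:1;O2/25:0
HexCer 18:1;O2/26:0
HexCer 18:1;O2/26:1
Hex2Cer 18:1;O2/16:0
Hex2Cer 18:1;O2/22:0
Hex2Cer 18:1;O2/24:0
Hex2Cer 18:1;O2/24:1
Hex2Cer 18:1;O2/26:0
GM3 18:1;O2/16:0
GM3 18:1;O2/24:0
GM3 18:1;O2/24:1
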