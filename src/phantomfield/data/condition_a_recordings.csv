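electrode,depth,delta_v_mV
Fp1,Z0,15800
Fp1,Z33,41200
Fp1,Z66,48400
Fp1,Z100,53200
Fpz,Z0,8080
Fpz,Z33,15600
Fpz,Z66,41600
Fpz,Z100,16600
Fp2,Z0,39600
Fp2,Z33,42800
Fp2,Z66,50400
Fp2,Z100,42400
F7,Z0,39200
F7,Z33,40800
F7,Z66,44000
F7,Z100,42400
F3,Z0,35600
F3,Z33,39600
F3,Z66,40400
F3,Z100,54000
Fz,Z0,32000
Fz,Z33,34400
Fz,Z66,44000
Fz,Z100,49600
F4,Z0,29200
F4,Z33,33600
F4,Z66,44400
F4,Z100,51600
F8,Z0,31600
F8,Z33,35600
F8,Z66,42800
F8,Z100,47600
T3,Z0,30800
T3,Z33,32000
T3,Z66,35200
T3,Z100,36800
C3,Z0,NR
C3,Z33,NR
C3,Z66,NR
C3,Z100,NR
Cz,Z0,28000
Cz,Z33,33200
Cz,Z66,43600
Cz,Z100,52000
C4,Z0,NR
C4,Z33,NR
C4,Z66,NR
C4,Z100,NR
T4,Z0,29200
T4,Z33,32000
T4,Z66,36800
T4,Z100,38000
T5,Z0,29600
T5,Z33,32800
T5,Z66,34800
T5,Z100,37600
P3,Z0,28000
P3,Z33,30000
P3,Z66,36000
P3,Z100,43200
Pz,Z0,24400
Pz,Z33,27600
Pz,Z66,34400
Pz,Z100,36700
P4,Z0,24000
P4,Z33,27200
P4,Z66,32400
P4,Z100,36800
T6,Z0,21600
T6,Z33,24800
T6,Z66,28000
T6,Z100,31600
O1,Z0,26400
O1,Z33,28800
O1,Z66,33200
O1,Z100,33200
Oz,Z0,22800
Oz,Z33,25200
Oz,Z66,29200
Oz,Z100,33200
O2,Z0,22000
O2,Z33,24400
O2,Z66,28800
O2,Z100,34800
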