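patient,gprWA,gprWG,gprGA,agv_cc
Patient 1,73,89,83,224.58
Patient 2,94,100,93,0.36
Patient 3,94,99,92,20.43
Patient 4,83,96,86,62.47
Patient 5,78,87,85,178.49
Patient 6,84,94,85,58.44
Patient 7,90,99,91,40.04
Patient 8,70,88,81,135.64
Patient 9,79,90,86,137.2
Patient 10,87,98,86,24.26
Patient 11,87,94,90,129.71
Patient 12,91,98,91,35.44
Patient 13,95,100,92,16.46
Patient 14,94,98,96,20.94
Patient 15,70,86,81,162.14
Patient 16,69,86,80,183.48
Patient 17,75,94,83,91.87
Patient 18,40,69,57,432.63
Patient 19,92,99,91,26.72
Patient 20,91,95,95,49.09
Patient 21,70,85,79,172.98
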