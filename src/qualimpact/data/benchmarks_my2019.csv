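measure_id,segment,p25,p50,p66,p75,p90
crc_screening,Medicare,67,74,78,80,83
crc_screening,Medicaid,,,,,
crc_screening,Marketplace,47,55,61,63,69
crc_screening,Commercial,57,62,66,68,74
crc_screening,CA-Marketplace,47,54,57,60,65
bp_control,Medicare,65,71,74,76,81
bp_control,Medicaid,53,61,65,67,72
bp_control,Marketplace,54,62,66,70,75
bp_control,Commercial,52,60,64,67,74
bp_control,CA-Marketplace,57,65,66,68,76
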