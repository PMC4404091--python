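subject,age,sex,location,size_mm,ruptured,followup_months,cohort
01 (RE),72,F,L paraophthalmic,26x17,Unruptured,10.5,recurrence
02 (RE),58,F,L MCA,16x11,Unruptured,5.8,recurrence
03 (RE),51,F,L vertebral,14x11,Unruptured,6.7,recurrence
04 (RE),50,M,Acom,4x13,Unruptured,18.6,recurrence
05 (RE),53,F,Acom,10x8,Unruptured,24.3,recurrence
06 (RE),60,F,R pcom,9x8,Unruptured,16.8,recurrence
07 (RE),46,F,L cavernous ICA,7x8,Unruptured,6.6,recurrence
08 (RE),49,F,Basilar tip,6x6,Unruptured,5.9,recurrence
09 (RE),47,M,Basilar tip,22x15,Ruptured,5.3,recurrence
10 (RE),59,F,R pcom,16x11,Ruptured,11.5,recurrence
11 (RE),22,M,R MCA terminus,7x10,Ruptured,4.3,recurrence
12 (RE),58,M,Acom,5x10,Ruptured,5.7,recurrence
13 (RE),68,F,Acom,9x8,Ruptured,12.1,recurrence
14 (RE),61,F,Basilar tip,6x6,Ruptured,2.0,recurrence
15 (RE),52,F,Acom,4x4,Ruptured,5.8,recurrence
16 (C),37,F,L ophthalmic,9x9,Unruptured,5.4,control
17 (C),50,F,L paraophthalmic,9x8,Unruptured,5.5,control
18 (C),50,F,L cavernous ICA,8x8,Unruptured,5.5,control
19 (C),69,F,R ICA,7x7,Unruptured,19.7,control
20 (C),40,F,R paraophthalmic,7x7,Unruptured,6.5,control
21 (C),16,F,R cavernous ICA,5x3,Unruptured,6.4,control
22 (C),47,F,R ICA terminus,4x4,Unruptured,22.6,control
23 (C),69,F,R ICA,2x3,Unruptured,19.7,control
24 (C),65,F,R pcom,8x3,Ruptured,8.2,control
25 (C),61,F,R pcom,6x5,Ruptured,6.3,control
26 (C),45,F,Basilar tip,5x4,Ruptured,14.7,control
27 (C),45,F,Acom,3x5,Ruptured,6.7,control
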