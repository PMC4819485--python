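# Hearing-impairment grading bands on the four-frequency pure-tone average (dB HL).
# WHO bands: WHO 1997 grades of hearing impairment (better ear).
# EU bands: European Working Group on Genetics of Hearing Impairment (Martini 1996),
# severe band 70-94 dB HL.
scale,grade_index,label,lower_db,upper_db
WHO,0,no impairment,-10,25
WHO,1,slight impairment,26,40
WHO,2,moderate impairment,41,60
WHO,3,severe impairment,61,80
WHO,4,profound impairment,81,120
EU,0,normal hearing,-10,19
EU,1,mild impairment,20,39
EU,2,moderate impairment,40,69
EU,3,severe impairment,70,94
EU,4,profound impairment,95,120
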