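# Median age-related hearing threshold shift coefficients alpha (dB/year^2):
# shift(age) = alpha * (age - 18)^2 for age >= 18, per the ISO 7029 quadratic model.
# Transcribed from the ISO 7029:2000 median (a_md) coefficient table.
sex,frequency_khz,alpha,edition_label
male,0.125,0.0030,ISO 7029:2000 median
male,0.25,0.0030,ISO 7029:2000 median
male,0.5,0.0035,ISO 7029:2000 median
male,1,0.0040,ISO 7029:2000 median
male,1.5,0.0055,ISO 7029:2000 median
male,2,0.0070,ISO 7029:2000 median
male,3,0.0115,ISO 7029:2000 median
male,4,0.0160,ISO 7029:2000 median
male,6,0.0180,ISO 7029:2000 median
male,8,0.0220,ISO 7029:2000 median
female,0.125,0.0030,ISO 7029:2000 median
female,0.25,0.0030,ISO 7029:2000 median
female,0.5,0.0035,ISO 7029:2000 median
female,1,0.0040,ISO 7029:2000 median
female,1.5,0.0050,ISO 7029:2000 median
female,2,0.0060,ISO 7029:2000 median
female,3,0.0075,ISO 7029:2000 median
female,4,0.0090,ISO 7029:2000 median
female,6,0.0120,ISO 7029:2000 median
female,8,0.0150,ISO 7029:2000 median
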