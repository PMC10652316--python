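study_id,year,design,country,ethnicity,gene,variant,n_cases,n_controls,model,or_point,ci_low,ci_high
Cai 2006,2006,population_case_control,China,Asian,ALDH2,rs671,81,162,additive,1.72,0.85,3.48
Cui 2009,2009,gwas,Japan,Asian,ADH1B,rs1042026,1067,2763,allelic,1.83,1.57,2.14
Cui 2009,2009,gwas,Japan,Asian,ADH1B,rs1042026,1067,2763,additive,3.48,2.33,5.20
Cui 2009,2009,gwas,Japan,Asian,ADH1B,rs1159918,1067,2763,allelic,1.88,1.59,2.21
Cui 2009,2009,gwas,Japan,Asian,ADH1B,rs1159918,1067,2763,additive,4.02,2.54,6.37
Cui 2009,2009,gwas,Japan,Asian,ADH1B,rs1229984,1067,2763,allelic,1.79,1.69,1.88
Cui 2009,2009,gwas,Japan,Asian,ADH1B,rs1229984,1067,2763,additive,4.10,3.24,5.18
Cui 2009,2009,gwas,Japan,Asian,ALDH2,rs671,1067,2763,allelic,1.67,1.58,1.76
Cui 2009,2009,gwas,Japan,Asian,ALDH2,rs671,1067,2763,additive,0.47,0.28,0.78
Gao 2013,2013,hospital_case_control,China,Asian,ADH1B,rs1229984,2098,2263,allelic,1.24,1.13,1.36
Gao 2013,2013,hospital_case_control,China,Asian,ADH1B,rs1229984,2098,2263,additive,1.54,1.25,1.89
Gao 2013,2013,hospital_case_control,China,Asian,ALDH2,rs671,2098,2263,allelic,0.83,0.75,0.91
Gao 2013,2013,hospital_case_control,China,Asian,ALDH2,rs671,2098,2263,additive,0.64,0.51,0.82
Guo 2013,2013,hospital_case_control,China,Asian,ADH1B,rs1229984,80,480,additive,1.46,0.71,2.59
Li 2011,2011,population_case_control,China,Asian,ALDH2,rs674,226,246,additive,3.38,1.64,6.95
Liu 2017,2017,hospital_case_control,China,Asian,ALDH2,rs671,37,31,additive,0.78,0.12,5.01
Liu 2017,2017,hospital_case_control,China,Asian,ALDH2,rs4767364,37,31,additive,1.21,0.16,9.08
Suo 2019,2019,population_case_control,China,Asian,ADH1B,rs1042026,1448,1992,additive,0.54,0.39,0.76
Suo 2019,2019,population_case_control,China,Asian,ADH1B,rs17033,1448,1992,additive,2.60,1.40,4.97
Suo 2019,2019,population_case_control,China,Asian,ALDH2,rs671,1448,1992,additive,0.58,0.38,0.85
Wang 2014,2014,hospital_case_control,China,Asian,ADH1B,rs1042026,615,537,additive,5.40,3.19,9.11
Wang 2011,2011,hospital_case_control,China,Asian,ADH1B,unnamed,81,162,allelic,1.51,0.93,2.37
Wang 2011,2011,hospital_case_control,China,Asian,ALDH2,rs674,81,162,allelic,1.73,0.81,2.79
Wang 2011,2011,hospital_case_control,China,Asian,ALDH2,rs674,81,162,additive,0.65,0.22,2.18
Yao 2018,2018,gwas,China,Asian,ADH1B,rs1042026,1033,2285,allelic,1.02,0.94,1.11
Yao 2018,2018,gwas,China,Asian,ALDH2,rs671,1033,2285,allelic,0.56,0.46,0.68
Yao 2018,2018,gwas,China,Asian,ALDH2,rs4767364,1033,2285,allelic,1.06,0.93,1.21
Ye 2014,2014,hospital_case_control,China,Asian,ADH1B,rs1229984,1001,1391,additive,2.81,2.18,3.62
Chen 2006,2006,hospital_case_control,China,Asian,ADH1B,rs1229984,330,592,additive,5.65,3.67,8.69
Chen 2006,2006,hospital_case_control,China,Asian,ALDH2,rs674,330,592,additive,0.78,0.38,1.62
Kagemoto 2016,2016,population_case_control,Japan,Asian,ALDH2,rs671,117,1125,allelic,2.02,1.30,3.14
Kagemoto 2016,2016,population_case_control,Japan,Asian,ADH1B,rs1229984,117,1125,allelic,2.05,1.32,3.20
Yokoyama 2006,2006,hospital_case_control,Japan,Asian,ADH1B,rs1229984,52,412,additive,0.48,0.18,1.31
Yokoyama 2006,2006,hospital_case_control,Japan,Asian,ALDH2,rs674,52,412,additive,1.49,0.47,4.78
Gu 2012,2012,hospital_case_control,China,Asian,ADH1B,rs1229984,380,380,additive,2.35,1.40,3.93
Gu 2012,2012,hospital_case_control,China,Asian,ALDH2,rs886205,380,380,allelic,0.58,0.34,0.87
Bye 2011,2011,population_case_control,South Africa,African,ADH1B,rs1229984,201,427,allelic,0.52,0.32,0.86
Bye 2011,2011,population_case_control,South Africa,African,ALDH2,rs886205,201,427,allelic,0.70,0.55,0.89
Tanaka 2012,2012,hospital_case_control,Japan,Asian,ADH1B,rs1229984,168,1083,allelic,1.82,1.63,2.03
Tanaka 2012,2012,hospital_case_control,Japan,Asian,ADH1B,rs1229984,168,1083,additive,4.08,3.27,5.09
Tanaka 2012,2012,hospital_case_control,Japan,Asian,ALDH2,rs671,742,820,allelic,1.78,1.60,1.98
Tanaka 2012,2012,hospital_case_control,Japan,Asian,ALDH2,rs671,742,820,additive,3.54,3.04,4.14
Yokoyama 2002,2002,hospital_case_control,Japan,Asian,ALDH2,rs674,234,634,additive,7.83,1.33,46.08
Yokoyama 2003,2003,population_case_control,Japan,Asian,ALDH2,rs674,65,206,additive,1.07,0.95,1.22
Ma 2010,2010,hospital_case_control,China,Asian,ALDH2,rs886205,128,326,allelic,1.63,1.16,2.28
Chen 2019,2019,population_case_control,South Africa,African,ALDH2,rs4767364,591,852,allelic,1.17,0.95,1.44
Ding 2009,2009,population_case_control,China,Asian,ALDH2,rs671,191,221,allelic,2.15,1.57,2.95
Ding 2009,2009,population_case_control,China,Asian,ALDH2,rs671,191,221,additive,5.69,2.51,12.18
Yang 2007,2007,hospital_case_control,China,Asian,ALDH2,rs674,191,198,allelic,1.05,0.76,1.44
Yang 2007,2007,hospital_case_control,China,Asian,ALDH2,rs674,191,198,additive,0.26,0.06,1.09
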