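gene,variant,model,minor_major,n_cases,n_controls,amount_grade,study_ids
ALDH2,rs671,additive,G > A,4655,6941,B,Cui 2009;Gao 2013;Suo 2019;Liu 2017
ADH1B,rs1229984,additive,T > C,5176,7364,A,Cui 2009;Gao 2013;Guo 2013;Ye 2014;Chen 2006;Gu 2012;Tanaka 2012;Yokoyama 2006
ADH1B,rs1042026,additive,T > A,4581,5365,B,Cui 2009;Suo 2019;Wang 2014
ALDH2,rs674,additive,G > A,1179,2471,B,Li 2011;Chen 2006;Wang 2011;Yokoyama 2002;Yokoyama 2003;Yokoyama 2006;Yang 2007
ALDH2,rs671,allelic,G > A,5248,9477,A,Cui 2009;Gao 2013;Kagemoto 2016;Tanaka 2012;Ding 2009;Yao 2018
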