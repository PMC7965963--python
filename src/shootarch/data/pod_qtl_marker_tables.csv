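qtl_chrom,qtl_pos,marker_id,high_nr,high_ref,low_nr,low_ref,reported_p
Gm11,15649090,ss715609881,11,1,0,12,9.6e-06
Gm15,5252046,ss715622826-7,3,9,11,1,2.8e-03
Gm18,55626229,ss715632229,5,7,12,0,4.6e-03
Gm11,5338661,ss715610851-6,8,4,1,11,9.4e-03
Gm02,40368201,ss715582578,6,6,12,0,1.4e-02
Gm11,33902439,ss715610584,8,4,2,10,3.6e-02
Gm18,55662445,ss715632230,7,5,12,0,3.7e-02
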