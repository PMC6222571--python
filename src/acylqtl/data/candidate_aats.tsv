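annotation	gene_id	chrom	start	end
Transferase	GRMZM2G387394	1	300173138	300174772
Malonyl-CoA:anthocyanin 5-O-glucoside-6'''-O-malonyltransferase-like	GRMZM2G341253	2	165106367	165108162
Anthocyanin 5-aromatic acyltransferase	GRMZM2G075513	4	170843898	170845760
Malonyl-CoA:anthocyanidin 5-O-glucoside-6'''-O-malonyltransferase-like	GRMZM2G316787	4	174072855	174074677
HXXXD-type acyltransferase	GRMZM2G382785	5	50372211	50374054
HXXXD-type acyltransferase	GRMZM2G436404	6	19122956	19124662
Anthocyanidin 3-O-glucoside 6''-O-acyltransferase-like	GRMZM2G095340	6	72337117	72341167
Transferase family protein	GRMZM5G800407	10	142328397	142330129
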