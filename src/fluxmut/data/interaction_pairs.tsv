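# Combined-mutant genotypes and the single-mutant (or component) genotypes
# whose relative rates define the sum and product expectations for the
# interaction classifier.  Component genotypes are separated by " + ".
combined	components
hst3 hst4	hst3 + hst4
hst3 hst4 rtt109	hst3 hst4 + rtt109
hst3 hst4 H3K56R	hst3 hst4 + H3K56R
hst3 hst4 H3K56Q	hst3 hst4 + H3K56Q
hst1 H3K56Q	hst1 + H3K56Q
hst3 hst4 hst1	hst3 hst4 + hst1
hst3 hst4 hst1 hst2	hst3 hst4 hst1 + hst2
hst3 hst4 hst2	hst3 hst4 + hst2
rtt109 H3K56R	rtt109 + H3K56R
msh2 rtt109	msh2 + rtt109
msh2 H3K56R	msh2 + H3K56R
msh2 asf1	msh2 + asf1
pol2-4 rtt109	pol2-4 + rtt109
pol2-4 H3K56R	pol2-4 + H3K56R
pol2-4 asf1	pol2-4 + asf1
pol3-5DV rtt109	pol3-5DV + rtt109
pol3-5DV H3K56R	pol3-5DV + H3K56R
pol3-5DV asf1	pol3-5DV + asf1
rev3 hst3 hst4	rev3 + hst3 hst4
rtt101 hst3 hst4	rtt101 + hst3 hst4
ctf18 hst3 hst4	ctf18 + hst3 hst4
rev3 rtt109	rev3 + rtt109
rad51 rtt109	rad51 + rtt109
rad52 rtt109	rad52 + rtt109
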