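# Golden encoding fixture: 17 variant records with their published tag (d)
# and value (alpha) encodings at n_SNP = 10.  Tests recompute both columns
# from CHROM/POS/REF/ALT and compare.
CHROM	POS	d	REF	ALT	alpha
1	161235340	3869648161	G	A	12582916
1	161235596	3869654305	C	T	14680069
1	161235657	3869655769	G	T	12582917
1	161235981	3869663545	G	A	12582916
1	161237503	3869700073	.	TTTTTGT	21849
1	161237891	3869709385	G	A	12582916
1	161238009	3869712217	G	.	12582912
1	161238488	3869723713	A	G	8388614
1	161238683	3869728393	G	A	12582916
1	161238856	3869732545	T	.	10485760
1	161239028	3869736673	AG	.	37748736
1	161239142	3869739409	A	G	8388614
1	161239346	3869744305	G	T	12582917
1	161239470	3869747281	C	T	14680069
1	161239788	3869754913	.	AA	16
1	161239978	3869759473	G	T	12582917
1	161240641	3869775385	TGAT	.	740294656
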