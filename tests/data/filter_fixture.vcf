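##fileformat=VCFv4.2
##FILTER=<ID=PASS,Description="All filters passed">
##contig=<ID=gene1,length=100>
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##INFO=<ID=AO,Number=A,Type=Integer,Description="Alternate allele observation count">
##INFO=<ID=RO,Number=1,Type=Integer,Description="Reference allele observation count">
##INFO=<ID=SAF,Number=A,Type=Integer,Description="Alt observations on the forward strand">
##INFO=<ID=SAR,Number=A,Type=Integer,Description="Alt observations on the reverse strand">
##INFO=<ID=SRF,Number=1,Type=Integer,Description="Ref observations on the forward strand">
##INFO=<ID=SRR,Number=1,Type=Integer,Description="Ref observations on the reverse strand">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO
gene1	10	.	A	G	.	.	DP=10000;AO=2;RO=9998;SAF=1;SAR=1;SRF=4999;SRR=4999
gene1	11	.	A	G	.	.	DP=10000;AO=2;RO=9998;SAF=1;SAR=1;SRF=4999;SRR=4999
gene1	12	.	A	G	.	.	DP=10000;AO=2;RO=9998;SAF=1;SAR=1;SRF=4999;SRR=4999
gene1	13	.	A	G	.	.	DP=10000;AO=2;RO=9998;SAF=1;SAR=1;SRF=4999;SRR=4999
gene1	20	.	C	T	.	.	DP=10000;AO=50;RO=9950;SAF=25;SAR=25;SRF=4975;SRR=4975
gene1	21	.	C	T	.	.	DP=10000;AO=50;RO=9950;SAF=25;SAR=25;SRF=4975;SRR=4975
gene1	22	.	C	T	.	.	DP=10000;AO=50;RO=9950;SAF=25;SAR=25;SRF=4975;SRR=4975
gene1	23	.	C	T	.	.	DP=10000;AO=50;RO=9950;SAF=25;SAR=25;SRF=4975;SRR=4975
gene1	24	.	C	T	.	.	DP=10000;AO=50;RO=9950;SAF=25;SAR=25;SRF=4975;SRR=4975
gene1	30	.	G	GA	.	.	DP=6000;AO=30;RO=5970;SAF=30;SAR=0;SRF=2985;SRR=2985
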