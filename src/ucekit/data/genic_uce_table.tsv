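chromosome	start	end	name	symbol	fbid
chr2L	2785538	2785672	chr2L.2	Syt1	FBgn0004242
chr2L	4314519	4314622	chr2L.4	tutl	FBgn0010473
chr2L	14089129	14089263	chr2L.5	nAcRalpha-34e	FBgn0028875
chr2R	10179256	10179343	chr2R.1	Ih	FBgn0263397
chr2R	20614061	20614184	chr2R.2	CG33988	FBgn0053988
chr3L	9148233	9148339	chr3L.1	Rdl	FBgn0004244
chr3L	12840178	12840256	chr3L.2	CG10948	FBgn0036317
chr3R	15589319	15589395	chr3R.2	GluClalpha	FBgn0024963
chr3R	20500491	20500603	chr3R.3	slo	FBgn0003429
chr3R	20508039	20508121	chr3R.4	slo	FBgn0003429
chr3R	27180238	27180336	chr3R.5	CG34347	FBgn0003429
chr3R	27663491	27663549	chr3R.6	RhoGAP100F	FBgn0039883
chrX	3678660	3678739	chrX.1	tlk	FBgn0086899
chrX	5293623	5293703	chrX.2	SK	FBgn0029761
chrX	14893890	14893967	chrX.3	eag	FBgn0000535
chrX	16365287	16365370	chrX.4	para	FBgn0264255
chrX	16367614	16367806	chrX.5	para	FBgn0264255
chrX	16371485	16371604	chrX.6	para	FBgn0264255
chrX	16403608	16403737	chrX.7	para	FBgn0264255
chrX	16408137	16408217	chrX.8	para	FBgn0264255
chrX	17845447	17845546	chrX.9	Sh	FBgn0003380
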