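# synthetic ClinVar-style annotation table (frozen stand-in)
pos	ref	alt	variant_type	rsid	clinvar_id	significance	diagnoses
15301	G	A	SNV	rs193302991	140591	Conflicting interpretations of pathogenicity	Familial cancer of breast
14783	T	C	SNV	rs193302982	140588	Conflicting interpretations of pathogenicity	Familial cancer of breast
15452	C	A	SNV	rs193302994	143925	Benign	Neoplasm of ovary|Leigh syndrome
3010	G	A	SNV	rs3928306	441149	Drug response	Not provided
13708	G	A	SNV	rs28359178	9696	Benign	Leber's optic atrophy|Leigh syndrome
489	T	C	SNV	rs28625645	434926	Benign	Leigh syndrome
10400	C	T	SNV	rs28358278	434744	Benign	Leigh syndrome|Familial cancer of breast
961	T	G	SNV	rs3888511	9627	Pathogenic	Nonsyndromic sensorineural mitochondrial deafness
15511	T	C	SNV	rs193302997	143928	Pathogenic	Neoplasm of ovary
951	G	A	SNV	rs199474663	434925	Pathogenic	Not provided
980	T	C	SNV	rs199474664	434927	Pathogenic	Not provided
1008	A	G	SNV	rs199474665	434928	Pathogenic	Not provided
8410	C	T	SNV	rs199474666	434929	Pathogenic	Not provided
11560	A	G	SNV	rs199474667	434930	Pathogenic	Not provided
14470	T	A	SNV	rs199474668	434931	Pathogenic	Not provided
15262	T	C	SNV	rs199474669	434932	Pathogenic	Not provided
15514	T	C	SNV	rs199474670	434933	Pathogenic	Not provided
15833	C	T	SNV	rs199474671	434934	Pathogenic	Not provided
9906	G		del	rs869183622	440701	Likely benign	Not provided
10151	A		del	rs869183623	440702	Likely benign	Not provided
9916	C		del	rs869183624	440703	Likely benign	Not provided
2193	T		del	rs869183625	440704	Likely benign	Not provided
9808		T	ins	rs869183626	440705	Likely benign	Not provided
750	A	G	SNV	rs2853518	441147	Benign	Not provided
2706	A	G	SNV	rs2854128	441148	Benign	Not provided
263	A	G	SNV	rs2853515	441146	Benign	Not provided
15326	A	G	SNV	rs2853508	9944	Benign	Familial cancer of breast|Leigh syndrome
12705	C	T	SNV	rs2854122	441150	Benign	Resistance to Parkinson disease
11719	G	A	SNV	rs2853495	441151	Benign	Juvenile myopathy, encephalopathy, lactic acidosis and stroke
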