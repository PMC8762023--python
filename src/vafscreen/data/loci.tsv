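name	chrom	pos	ref	region	alt	cdna_pos	codon_context
T635C	chr2	39477124	A	UTR3	G	3320
A644C	chr2	39477115	T	UTR3	G	3329
A410T	chr2	39519957	C	CDS	T	1228	GCA
K650R	chr2	39499448	T	CDS	C	1949	AAA
L267Ter	chr2	39552878	A	CDS	T	800	TTA
T875S	chr2	39477820	G	CDS	C	2624	ACC
C675W	chr2	39494337	A	CDS	C	2025	TGT
A546T	chr2	39507491	C	CDS	T	1636	GCA
A579T	chr2	39505607	C	CDS	T	1735	GCC
M220V	chr2	39553291	T	CDS	C	658	ATG
F215S	chr2	39553305	A	CDS	G	644	TTT
A199T	chr2	39553354	C	CDS	T	595	GCA
P704Q	chr2	39492369	G	CDS	T	2111	CCA
D634Y	chr2	39499497	C	CDS	A	1900	GAT
P436L	chr2	39517440	G	CDS	A	1307	CCG
M90I	chr2	39570569	C	CDS	T	270	ATG
G78V	chr2	39583402	C	CDS	A	233	GGT
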