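variant	cdna	sex	eeg	mri	development	diagnosis	inheritance	af_v4	af_v2	source	label
p.Leu209Pro	c.626T>C	M	–	Abnormal	ID; dystonia	NDD without EP	De novo	–	–	30542205	pathogenic
p.Ala239Asp	c.716C>A	M	–	–	GDD	DEE	De novo	–	–	34055682	pathogenic
p.Leu247Pro	c.740T>C	F	Multifocal	Normal	GDD; dystonia	DEE	De novo	–	–	28235671	pathogenic
p.Ser323Ile	c.968G>T	M	–	–	GDD	DEE	De novo	–	–	34145886	pathogenic
p.Val423Met	c.1267G>A	M	–	–	DD; dystonia	NDD*	De novo	–	–	34490615	pathogenic
p.Leu850Pro	c.2549T>C	M	–	PMG	GDD; dystonia	NDD without EP	De novo	–	–	30146301	pathogenic
p.Leu855Pro	c.2564T>C	F	–	–	GDD; dystonia; spastic tetraplegia	NDD without EP	De novo	–	–	32515017	pathogenic
p.Ile875Thr	c.2624T>C	M	–	PMG	DD	DEE	De novo	–	–	29466837	pathogenic
p.Ile875Thr	c.2624T>C	F	–	PMG	DD	DEE	De novo	–	–	29466837	pathogenic
p.Ile875Thr	c.2624T>C	M	–	PMG, microcephaly	NDD; hypotonia; spastic tetraplegia	DEE	De novo	–	–	30146301	pathogenic
p.Ile875Thr	c.2624T>C	F	–	PMG, microcephaly	GDD; hypotonia; spastic tetraplegia	DEE	De novo	–	–	30146301	pathogenic
p.Ile875Thr	c.2624T>C	M	Multifocal	PMG	ID; dystonia	DEE	De novo	–	–	32515017	pathogenic
p.Ile875Thr	c.2624T>C	F	Multifocal	PMG	DD; hypotonia; spastic tetraplegia	DEE	De novo	–	–	32515017	pathogenic
p.Ile875Thr	c.2624T>C	F	Multifocal	PMG	Hypotonia; DD	DEE	De novo	–	–	32515017	pathogenic
p.Ile875Thr	c.2624T>C	M	–	PMG	ID; hypotonia; spastic	DEE	De novo	–	–	32515017	pathogenic
p.Ile875Thr	c.2624T>C	M	Multifocal	PMG	DD; hypotonia	DEE	De novo	–	–	32515017	pathogenic
p.Ile875Thr	c.2624T>C	M	Multifocal	PMG	GDD	DEE	De novo	–	–	29740860	pathogenic
p.Ile875Thr	c.2624T>C	M	Hypsarrhythmia, multifocal	PMG	GDD	DEE	De novo	–	–	29740860	pathogenic
p.Leu885Phe	c.2653C>T	F	Burst suppression, hypsarrhythmia	Frontal pachygyria; hypoplastic corpus callosum	DD; hypotonia; spastic tetraplegia	DEE	De novo	–	–	32515017	pathogenic
p.Pro1165Leu	c.3494C>T	F	Focal discharge	–	Normal	FE	Inherited from affected mother	0.000008058	0	34992632	pathogenic
p.Pro1333Leu	c.3998C>T	M	Hypsarrhythmia, multifocal	Normal	DD	DEE	De novo	–	–	29466837	pathogenic
p.Pro1333Leu	c.3998C>T	M	Hypsarrhythmia, multifocal	Hypoplastic corpus callosum	DD; hypotonia	DEE	De novo	–	–	32515017	pathogenic
p.Pro1333Leu	c.3998C>T	NA	–	–	DD	DEE	De novo	–	–	27848944	pathogenic
p.Ile1468Arg	c.4403T>G	F	Hypsarrhythmia, multifocal	Normal	DD; hypotonia	DEE	De novo	–	–	32515017	pathogenic
p.Thr1486Ile	c.4457C>T	M	Generalized discharges	PMG	Pseudobulbar palsy; ID	DEE	De novo	–	–	32515017	pathogenic
p.Arg1621Gln	c.4862G>A	M	Normal	PMG	ID	DEE	De novo	–	–	32515017	pathogenic
p.Arg1621Gln	c.4862G>A	M	–	PMG	GDD; aggressive behavior; ADHD	DEE	De novo	–	–	31618753	pathogenic
p.Phe1646Ser	c.4937T>C	F	Multifocal	PMG	Dysarthria; facial paresis; brisk reflexes; ID	DEE	De novo	–	–	32515017	pathogenic
p.Phe1646Cys	c.4937T>G	M	–	PMG	Pseudobulbar palsy; right hemiparesis; DD	NDD without EP	Inherited from affected mother	–	–	32515017	pathogenic
p.Phe1646Cys	c.4937T>G	F	–	PMG	Pseudobulbar palsy; brisk reflexes; ID	DEE	Inherited from affected mother	–	–	32515017	pathogenic
p.Tyr1669Cys	c.5006A>G	M	–	–	DD; ASD	NDD without EP	De novo	0.000001239	–	32515017	pathogenic
p.Asp1688Tyr	c.5062G>T	F	Multifocal	Normal	Normal	FE	Inherited from affected father	0.0000006195	0	33895391	pathogenic
p.Met1765Ile	c.5295G>A	M	–	PMG	hypotonia; DD.	DEE	De novo	–	–	32515017	pathogenic
p.Met1765Ile	c.5295G>A	M	Multifocal	PMG, hypoplastic corpus callosum	GDD; dyskinetic movements; cortical blindness; spastic tetraplegia	DEE	De novo	–	–	31677917	pathogenic
p.Val1769Ala	c.5306T>C	F	Multifocal	–	DD	DEE	De novo	–	–	29466837	pathogenic
p.Val1769Ala	c.5306T>C	F	Multifocal	–	DD	DEE	De novo	–	–	32515017	pathogenic
p.Val1769Ala	c.5306T>C	F	Hypsarrhythmia or generalized discharges	Normal	DD; hypotonia; ASD	DEE	De novo	–	–	32515017	pathogenic
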