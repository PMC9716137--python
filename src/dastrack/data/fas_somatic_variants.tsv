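exon	region	genomic_position_hg38	cdna_change	protein_change	variant_class	reference
2	Extracellular	chr10:89003098	c.100G>T	p.G34X	nonsense	B25
3	Extracellular	chr10:89007700	c.197G>A	p.G66D	missense	B26
3	Extracellular	chr10:89007835	c.332A>G	p.H111R	missense	B17
5	Extracellular	chr10:89010566	c.471C>A	p.C157X	nonsense	B26
6	Transmembrane	NA	NA	p.W189fs (stop at 225)	frameshift	B15
6	Transmembrane	NA	NA	p.W189fs (stop at 220)	frameshift	B16
7	Intracellular	chr10:89012061	c.631G>T	p.E211X	nonsense	B17
7	Intracellular	NA	NA	p.P217fs (stop at 220)	frameshift	B16
8	Intracellular	chr10:89012083	c.651+2T>C	p.P217fs	frameshift	B15
8	Intracellular	chr10:89013368	c.676+1G>A	p.E218MfsX4	frameshift	B17
8	Intracellular	chr10:89013334	c.652-9_653del	p.E218MfsX4	frameshift	B17
8	Intracellular	chr10:89013342	c.652-1G>T	p.E218MfsX4	frameshift	B17
8	Intracellular	chr10:89013367	c.676G>T	p.E218MfsX4	frameshift	B17
8	Intracellular	chr10:89013343	c.652G>T	p.E218X	nonsense	B17
8	Intracellular	chr10:89013348	c.657_658del	p.V220GfsX6	frameshift	B17
8	Intracellular	chr10:89013348	c.657_658delAG	p.V220GfsX6	frameshift	B27
8	Intracellular	chr10:89013359	c.668_675del	p.N223RfsX3	frameshift	B17
8	Intracellular	chr10:89013362	c.671T>G	p.L224X	nonsense	B17
8	Intracellular	chr10:89013365	c.674C>A	p.S225Y	missense	B26
8	Intracellular	NA	NA	p.D226fs (stop at 277)	frameshift	B16
8	Intracellular	chr10:89013341	c.652-2A>T	Splice	splice	B27
8	Intracellular	chr10:89013342	c.652-1G>A	Splice	splice	B27
9	Intracellular	chr10:89014121	c.679delG	p.V227LfsX3	frameshift	B28
9	Intracellular	chr10:89014122	c.682_686del	p.D228EfsX2	frameshift	B17
9	Intracellular	chr10:89014128	c.686T>A	p.L229X	nonsense	B29
9	Intracellular (DD)	NA	NA	p.S230fs (stop at 243)	frameshift	B15
9	Intracellular (DD)	NA	NA	p.S230fs (stop at 240)	frameshift	B16
9	Intracellular (DD)	chr10:89014151	c.709G>C	p.A237P	missense	B25
9	Intracellular (DD)	chr10:89014154	c.712G>T	p.G238X	nonsense	B27
9	Intracellular (DD)	chr10:89014161	c.718_719insGTCG	p.M240SfsX8	frameshift	this_study
9	Intracellular (DD)	chr10:89014191	c.749G>A	p.R250Q	missense	B16
9	Intracellular (DD)	chr10:89014190	c.768C>G	p.R250G	missense	B27
9	Intracellular (DD)	chr10:89014221	c.779A>T	p.D260V	missense	B15
9	Intracellular (DD)	chr10:89014220	c.778G>A	p.D260N	missense	B17
9	Intracellular (DD)	chr10:89014221	c.779A>G	p.D260G	missense	B29
9	Intracellular (DD)	chr10:89014220	c.778G>T	p.D260Y	missense	B27
9	Intracellular (DD)	chr10:89014251	c.812_814del	p.A271del	inframe_deletion	B27
9	Intracellular (DD)	chr10:89014257	c.815A>G	p.E272G	missense	B27
9	Intracellular (DD)	chr10:89014259	c.817C>A	p.Q273K	missense	B16
9	Intracellular (DD)	NA	NA	p.V275fs (stop at 280)	frameshift	B25
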