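level1	level2	label
1	*	Extracellular signal reception events
1	1	Physical stimulation of receptors
1	2	Binding with hormones
1	3	Binding with non-growth factor cytokines
1	4	Binding with growth factors
1	5	Binding with neuronal receptors
1	6	Binding with other ligands
2	*	Plasma membrane transduction events
2	1	Channel operation
2	2	Ion channel transduction
2	3	G-protein transduction
2	4	Other Ser/Thr phosphorylation
2	5	Tyr phosphorylation
2	6	Cleavage
2	7	Others
3	*	Plasma membrane to cytoplasm transduction events
3	1	Membrane receptor releasing
3	2	Protein–protein interaction
4	*	Intracellular signal transduction events
4	1	Ser/Thr phosphorylation
4	2	Tyr phosphorylation
4	3	Other phosphorylation
4	4	Dephosphorylation
4	5	Ubiquitination
4	6	Methylation
4	7	Deamination
4	8	Nitrosylation
4	9	GDP/GTP conversion
4	10	Dimerization
4	11	Protein–protein interaction
4	12	Others
5	*	Cytoplasm to nucleoplasm transduction events
5	1	Others
6	*	Nucleoplasm to nucleoplasm transduction events
6	1	Binding with nuclear receptor
6	2	Binding with transcription factor
6	3	Acetylation
6	4	Deacetylation
6	5	Others
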