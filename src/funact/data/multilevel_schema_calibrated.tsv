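edge_type	src_type	dst_type	directed	oriented
CODA|BioGRID|undirected_link	molecule	molecule	0	1
CODA|RegNetwork|directed_link	molecule	molecule	1	0
CODA|TRANSFAC|directed_link	molecule	molecule	1	0
CODA|KEGG|directed_link	molecule	molecule	1	0
CODA|KEGG|undirected_link	molecule	molecule	0	1
CODA|KEGG|positive_increase	molecule	molecule	1	0
CODA|KEGG|positive_decrease	molecule	molecule	1	0
CODA|EndoNet|directed_link	molecule	molecule	1	0
CODA|EndoNet|directed_link	molecule	function	1	0
CODA|EndoNet|positive_increase	molecule	molecule	1	0
CODA|EndoNet|positive_increase	molecule	function	1	0
CODA|EndoNet|positive_decrease	molecule	molecule	1	0
CODA|EndoNet|positive_decrease	molecule	function	1	0
CODA|EndoNet|negative_increase	molecule	function	1	0
CODA|GO|undirected_link	molecule	function	0	1
CODA|PhenoGO|undirected_link	function	function	0	1
CODA|PhenoGO|undirected_link	function	phenotype	0	1
UMLS|NCI|undirected_link	molecule	function	0	1
UMLS|NCI|undirected_link	function	function	0	1
UMLS|NCI|undirected_link	function	phenotype	0	1
UMLS|NCI|undirected_link	phenotype	phenotype	0	1
UMLS|OMIM|undirected_link	function	phenotype	0	0
UMLS|OMIM|undirected_link	phenotype	phenotype	0	0
UMLS|MedlinePlus|undirected_link	function	phenotype	0	0
UMLS|MedlinePlus|undirected_link	phenotype	phenotype	0	0
UMLS|MTHMST|undirected_link	phenotype	phenotype	0	0
MEDLINE|MeSH|co_occurrence	function	function	0	0
MEDLINE|MeSH|co_occurrence	function	phenotype	0	0
MEDLINE|MeSH|co_occurrence	phenotype	phenotype	0	0
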