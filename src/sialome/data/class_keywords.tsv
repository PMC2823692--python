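# Closed classification vocabulary: housekeeping (H) subgroups and
# secreted (S) protein families, with lowercase substring keywords matched
# against best-hit descriptions (first matching row wins, '|'-separated).
major	subcategory	keywords
H	Protein synthesis machinery	ribosomal|ribosome|elongation factor|initiation factor|trna synthetase|aminoacyl
H	Unknown conserved	unknown conserved|conserved secreted protein
H	Transporters and storage	transporter|v-atpase|vacuolar atpase|ion channel|ferritin|porin
H	Energy metabolism	cytochrome c|cytochrome oxidase|nadh dehydrogenase|atp synthase|oxidoreductase
H	Protein modification machinery	protein disulfide|peptidylprolyl|protein kinase|glycosyltransferase|chaperonin|heat shock
H	Amino acid metabolism	aminotransferase|transaminase|glutamine synthetase|arginase
H	Signal transduction	g protein|signal transduc|calmodulin|14-3-3|rab gtpase
H	Carbohydrate metabolism	glycogen|aldolase|enolase|phosphoglycerate|glyceraldehyde
H	Protein export machinery	signal recognition particle|sec61|translocon|coatomer|signal peptidase
H	Cytoskeletal	actin|tubulin|myosin|profilin|dynein
H	Transcription machinery	rna polymerase|splicing factor|spliceosome|rna helicase
H	Lipid metabolism	fatty acid|lipase|acyl-coa|sterol carrier
H	Proteasome machinery	proteasome|ubiquitin
H	Extracellular matrix	collagen|laminin|cuticle protein
H	Nuclear regulation	histone|chromatin
H	Immunity	immune|toll pathway|relish|prophenoloxidase
H	Intermediate/secondary metabolism	cytochrome p450|glutathione s-transferase
H	Nucleic acid metabolism	dna polymerase|ribonucleotide reductase|dna ligase
H	Transcription factors	transcription factor|homeobox|zinc finger
S	Amylase/maltase/chitinase	amylase|maltase|chitinase|glucosidase|sugar hydrolase
S	Serine proteases	serine protease|trypsin|chymotrypsin
S	Adenosine deaminase	adenosine deaminase
S	Phosphatase	phosphatase
S	DNAse	dnase|endonuclease
S	Salivary immunity related products	lysozyme|lectin|gram-negative binding|antimicrobial
S	Antigen 5 family	antigen 5|antigen-5|ag5|ag-5
S	Mucins	mucin|peritrophin
S	Serpin	serpin
S	D7/OBP family	d7|odorant binding|odorant-binding
S	30 kDa antigen/Aegyptin	aegyptin|30 kda antigen|ge rich|ge-rich
S	6.3 kDa family	6.3 kda
S	30.5 kDa family	30.5 kda
S	23.4 kDa family	23.4 kda
S	41.9 kDa family	41.9 kda|41 kda|41.0 kda
S	62 kDa family	62 kda
S	Fragment of culicine salivary protein	culicine salivary protein
S	16.7 kDa family	16.7 kda|cwrp|cysteine and tryptophan rich
S	GQP repeat family	gqp repeat|gqg repeat|polyhistidine
S	9.7 kDa family	9.7 kda
S	4.2 kDa family	4.2 kda
S	HHI repeat family	hhi repeat
S	Cys rich family	cys rich|cys-rich|cysteine rich
S	7.8 kDa family	7.8 kda
S	Unknown secreted family
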