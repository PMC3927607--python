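# SUPERFAMILY/SCOP 1.73 two-tier functional annotation scheme: number of fold
# superfamilies (FSFs) per minor category, within 7 general categories.
# 1,646 annotated FSFs + 135 NONA (not annotated) = 1,781 total.
# FSF identities are not distributed with the scheme; fsfcensus expands these
# counts into deterministic synthetic placeholder keys (see io.default_scheme).
general_category	minor_category	n_fsf
Metabolism	Energy	54
Metabolism	Photosynthesis	20
Metabolism	E- transfer	31
Metabolism	Amino acids m/tr	20
Metabolism	Nitrogen m/tr	1
Metabolism	Nucleotide m/tr	30
Metabolism	Carbohydrate m/tr	30
Metabolism	Polysaccharide m/tr	21
Metabolism	Storage	0
Metabolism	Coenzyme m/tr	50
Metabolism	Lipid m/tr	17
Metabolism	Cell envelope m/tr	8
Metabolism	Secondary metabolism	11
Metabolism	Redox	55
Metabolism	Transferases	29
Metabolism	Other enzymes	156
General	Small molecule binding	27
General	Ion binding	13
General	Lipid/membrane binding	4
General	Ligand binding	3
General	General	28
General	Protein interaction	49
General	Structural protein	7
Information	Chromatin structure	7
Information	Translation	92
Information	Transcription	24
Information	DNA replication/repair	68
Information	RNA processing	10
Information	Nuclear structure	0
Other	Unknown function	200
Other	Viral proteins	73
Extracellular processes	Cell adhesion	31
Extracellular processes	Immune response	19
Extracellular processes	Blood clotting	5
Extracellular processes	Toxins/defense	40
Intracellular processes	Cell cycle, Apoptosis	20
Intracellular processes	Phospholipid m/tr	6
Intracellular processes	Cell motility	20
Intracellular processes	Trafficking/secretion	0
Intracellular processes	Protein modification	35
Intracellular processes	Proteases	52
Intracellular processes	Ion m/tr	21
Intracellular processes	Transport	54
Regulation	RNA binding, m/tr	19
Regulation	DNA-binding	66
Regulation	Kinases/phosphatases	15
Regulation	Signal transduction	53
Regulation	Other regulatory function	34
Regulation	Receptor activity	18
NONA	NONA	135
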