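gene	Bombyx mori	Tribolium castaneum	Drosophila melanogaster	Nilaparvata lugens	Caenorhabditis elegans
Argonaute-1	+,-	+,+	+,+	+,+	+,+
Argonaute-3	+,+	+,+	+,+	+,+	Homolog prg-1,+
Dicer-2	+,-	+,+	+,+	+,+	-,-
Dicer-1	-,-	+,+	+,+	+,+	+,+
Aubergine	+,-	+,-	+,+	+,+	Homolog prg-1,+
Drosha	-,-	+,+	+,+	+,+	+,+
Pasha	+,-	+,+	+,+	+,+	+,+
Loquacious	+,-	+,+	+,+	+,+	-,-
R2D2	+,-	+,+	+,+	+,+	-,-
Dbp45A subfamily	+,-	-,-	+,-	-,-	-,-
VASA subfamily	+,+	+,-	+,+	-,-	-,-
DDX18/HAS1 subfamily	+,-	-,-	+,-	-,-	+,-
U1A snRNP	-,-	+,-	+,-	-,-	+,-
SmG	+,-	+,-	+,-	-,-	+,-
Integrator complex subunit (Int11)	+,-	-,-	-,-	-,-	+,-
Zn finger protein	+,-	+,+	+,-	-,-	+,+
Regulator of nonsense transcripts 1 homolog (smg-2 like)	+,-	+,-	+,+	-,-	+,+
CaM Kinase	+,-	+,-	+,-	-,-	+,-
Serine/threonine p21-activated kinase (PAK) mbt like protein	+,-	+,-	+,-	-,-	+,-
cAMP-dependent protein kinase C1	+,-	+,-	+,-	-,-	+,-
Protein Kinase C	+,-	+,-	+,-	-,-	+,-
IKK-beta	+,-	+,-	+,-	-,-	+,-
STE20/Fray	-,-	+,-	+,-	-,-	-,-
MAPKK4	+,-	+,-	+,-	-,-	+,+
MDR1A	+,-	+,-	+,-	-,-	+,+
Tudor	+,+	+,-	+,+	-,-	+,+
Sil-2	+,+	+,+	-,-	+,+	+,+
Histone3 Lysine4 N-methyltransferase	-,-	-,-	+,+	-,-	+,+
Histone deacetylase 3 like	+,-	+,-	+,+	-,-	+,+
Gas41	+,-	+,-	+,-	-,-	-,-
eIF2B-gamma	+,-	+,-	+,-	-,-	+,+
eIF4AII	-,-	-,-	+,-	-,-	Homolog INF-1,-
eIF4AIII	+,-	+,-	+,-	-,-	+,-
RPL23A	+,-	+,-	+,-	-,-	+,+
KIF18A-like	+,-	+,-	-,-	-,-	+,-
Cyclin-dependent kinase 5 homolog	+,-	+,-	+,-	-,-	-,-
KIF3A-like	+,-	+,-	+,-	-,-	+,-
Isocitrate dehydrogenase	+,-	+,-	+,-	-,-	+,+
Myosin VIIa-like	+,-	+,-	+,-	-,-	+,-
Nucleolar complex protein 2 homolog	+,-	+,-	+,-	-,-	+,-
WD 40 like repeat domain	+,-	+,-	+,-	-,-	+,-
S-phase kinase-associated protein (SkpA)	+,-	+,-	+,-	-,-	+,-
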