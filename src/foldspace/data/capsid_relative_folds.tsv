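fold_id	fold_name	description	contains_capsid	example_relative	example_id
b.1	Immunoglobulin-like beta-sandwich	sandwich; 7 strands in 2 sheets; greek-key. some members of the fold have additional strands	Yes	Titin, I27	d1tiua_
b.2	Common fold of diphtheria toxin/transcription factors/cytochrome f	sandwich; 9 strands in 2 sheet; greek-key; subclass of immunoglobin-like fold	No	Runt-related transcription factor 1	d1eaqa_
b.6	Cupredoxin-like	sandwich; 7 strands in 2 sheets, greek-key variations: some members have additional 1-2 strands	No	Auracyanin	d1qhqa_
b.7	C2 domain-like	sandwich; 8 strands in 2 sheets; greek-key	No	Chaperone protein Caf1M	d1p5va2
b.14	Calpain large subunit, middle domain (domain III)	sandwich; 8 strands in 2 sheets; jelly-roll	No	M-Calpain	d1df0a2
b.18	Galactose-binding domain-like	sandwich; 9 strands in 2 sheets; jelly-roll	No	Xyn10B carbohydrate-binding module	d1h6ya_
b.22	TNF-like	sandwich, 10 strands in 2 sheets; jelly-roll	No	Tumor necrosis factor superfamily member 4	d2hewf1
b.23	CUB-like	sandwich, 10 strands in 2 sheets; jelly-roll	No	Acidic seminal fluid protein (spermadhesin)	d1sfpa_
b.29	Concanavalin A-like lectins/glucanases	sandwich; 12-14 strands in 2 sheets; complex topology	Yes	Sugar binding protein	d1is3a_
b.47	Trypsin-like serine proteases	barrel, closed; n = 6, S = 8; greek-key duplication: consists of two domains of the same fold	Yes	human alpha-thrombin	d1h8d.1
b.71	Glycosyl hydrolase domain	folded sheet; greek-key	No	alpha-galactosidase	d1uasa1
b.82	Double-stranded beta-helix	one turn of helix is made by two pairs of antiparallel strands linked with short turns has appearance of a sandwich of distinct architecture and jelly-roll topology	No	transcriptional regulator, HTH_3 family	d1y9qa2
b.121	Nucleoplasmin-like/VP (viral coat and capsid proteins)	sandwich; 8 strands in 2 sheets; jelly-roll; some members can have additional 1-2 strands characteristic interaction between the domains of this fold allows the formation of five-fold and pseudo six-fold assemblies	Yes	Nucleoplasmin-like protein (histone chaperone)	d1nlqa_
b.132	Supernatant protein factor (SPF), C-terminal domain	sandwich; 8 strands in 2 sheets; jelly-roll; similarity to the Nucleoplasmin-like/VP fold	No	Lipid Binding Protein	d1olma2
b.135	Superantigen (mitogen) Ypm	sandwich; 9 strands in 2 sheets; jelly-roll	No	superantigen from Yersinia pseudotuberculosis	d1pm4a_
c.2	NAD(P)-binding Rossmann-fold domains	core: 3 layers, a/b/a; parallel beta-sheet of 6 strands, order 321456	No	Shikimate dehydrogenase	d1nyta1
c.16	Lumazine synthase	3 layers, a/b/a; core: parallel beta-sheet of 4 strands, order 2134	No	lumazine synthase	d1ejba_
c.23	Flavodoxin-like	3 layers, a/b/a; parallel beta-sheet of 5 strand, order 21345	No	Lysine aminomutase	d1xrsb1
c.37	P-loop containing nucleoside triphosphate hydrolases	3 layers: a/b/a, parallel or mixed beta-sheets of variable sizes	No	elongation factor SelB	d1wb1a4
c.44	Phosphotyrosine protein phosphatases I-like	3 layers: a/b/a; parallel beta-sheet of 4 strands, order 2134	No	IIBcellobiose	d1iiba_
c.66	S-adenosyl-L-methionine-dependent methyltransferases	core: 3 layers, a/b/a; mixed beta-sheet of 7 strands, order 3214576; strand 7 is antiparallel to the rest	No	salicylic acid carboxyl methyltransferase	d1m6ex_
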