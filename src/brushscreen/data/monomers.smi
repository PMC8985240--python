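# The 14 hydrophilic polymer-brush monomers / repeating blocks.
# Format: SMILES<TAB>abbreviation ; full name and provenance in the trailing comment.
#
# The printed structure table of the source study is available only as an
# image; each SMILES below is therefore the standard literature structure
# for the named monomer (reconstructed, not transcribed — see package docs).
# OZ is drawn as the linear N-acylated repeat unit of poly(2-methyl-2-
# oxazoline), consistent with the study's description of OZ as a linear
# molecule; HEMA is drawn as the methacrylAMIDE, following the study's
# expansion "hydroxyethyl methacrylamide"; CBAA/CBMA use the 2-carbon
# carboxybetaine arm common to betaine monomer chemistry.
CCN(C)C(C)=O	OZ	# oxazoline (poly(2-methyl-2-oxazoline) repeating block, linear)
C=CC(N)=O	AA	# acrylamide
C=CN1CCCC1=O	VP	# vinylpyrrolidone (N-vinyl-2-pyrrolidone)
OCC(O)CO	Gly	# glycerol
C=CC(=O)N1CCOCC1	AcM	# acryloyl morpholine (4-acryloylmorpholine)
C=CC(=O)N(C)C	DMA	# dimethyl acrylamide (N,N-dimethylacrylamide)
C=C(C)C(=O)NCC(C)O	HPMA	# hydroxypropyl methacrylamide (N-(2-hydroxypropyl)methacrylamide)
C=C(C)C(=O)NCCO	HEMA	# hydroxyethyl methacrylamide (N-(2-hydroxyethyl)methacrylamide)
CC(=O)NC1C(O)CC(O)(C(=O)O)OC1C(O)C(O)CO	SA	# sialic acid (N-acetylneuraminic acid, pyranose form, stereocenters omitted)
C=CC(=O)NCCC[N+](C)(C)CCC(=O)[O-]	CBAA	# carboxybetaine acrylamide (3-[[3-(acrylamido)propyl]dimethylammonio]propanoate)
C=C(C)C(=O)OCC[N+](C)(C)CCC(=O)[O-]	CBMA	# carboxybetaine methacrylate (3-[[2-(methacryloyloxy)ethyl]dimethylammonio]propanoate)
C=C(C)C(=O)OCC[N+](C)(C)CCCS(=O)(=O)[O-]	SBMA	# sulfobetaine methacrylate (3-[[2-(methacryloyloxy)ethyl]dimethylammonio]propane-1-sulfonate)
C=C(C)C(=O)OCCOP(=O)([O-])OCC[N+](C)(C)C	MPC	# methacryloyloxyethyl phosphorylcholine (2-(methacryloyloxy)ethyl phosphorylcholine)
C=Cc1cc[n+](CCCS(=O)(=O)[O-])cc1	VPPS	# vinyl-pyridinio propanesulfonate (3-(4-vinylpyridinium-1-yl)propane-1-sulfonate)
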