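taxon	origin	COI	EF-1a	GAPDH	wingless
Coenonympha orientalis	Greece	MN829478	MN829462
Glaucopsyche paphos	Cyprus	MN829481	MN829463
Gonepteryx maderensis	Portugal: Madeira	MN829482	MN829464
Hipparchia azorina	Portugal: Azores	MN829483	MN829465
Hipparchia bacchus	Spain: Canary Islands	MN829484	MN829466
Hipparchia cretica	Greece: Crete	MN752718	MN829467	MN752786	MN752837
Hipparchia gomera	Spain: Canary Islands	MN829485	MN829468
Hipparchia maderensis	Portugal: Madeira	MN829486
Hipparchia mersina	Greece: Samos	MN752720	MN829469	MN752785	MN752836
Hipparchia miguelensis	Portugal: Madeira	MN829487
Hipparchia sbordonii	Italy: Pontine Islands	MN752723
Hipparchia tamadabae	Spain: Canary Islands	MN829488
Hipparchia tilosi	Spain: Canary Islands	MN829489
Hipparchia wyssii	Spain: Canary Islands	MN829490	MN829470
Lycaena bleusei	Spain	MN829492
Pieris balcana	North Macedonia	KC462788
Pieris wollastoni	Portugal: Madeira	KC462820
Thymelicus christi	Spain: Canary Islands	MN829496
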