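taxon	rank	mean_copies
Leisingera	genus	2.0
Phaeobacter	genus	3.0
Sulfitobacter	genus	4.0
Antarctobacter	genus	2.0
Sphingomonas	genus	2.0
Hyphomonas	genus	2.0
Parvibaculum	genus	2.0
Sneathiella	genus	2.0
Alteromonas	genus	5.0
Glaciecola	genus	4.0
Marinobacter	genus	3.0
Pseudoalteromonas	genus	9.0
Alcanivorax	genus	3.0
Marinomonas	genus	8.0
Pseudohongiella	genus	2.0
Methylophaga	genus	3.0
Spongiibacter	genus	2.0
Winogradskyella	genus	2.0
Allomuricauda	genus	2.0
Crocinitomix	genus	2.0
Balneola	genus	2.0
Thalassospira	genus	2.0
Pelagibacter	genus	1.0
Nitrosopumilus	genus	1.0
Actinomarina	genus	1.0
Synechococcus	genus	2.0
Paludisphaera	genus	2.0
Pseudomonas	genus	4.5
Vibrio	genus	9.0
Cryomorphaceae	family	2.0
Lentimicrobiaceae	family	1.5
Rhodobacteraceae	family	2.5
Pirellulaceae	family	1.5
Flavobacteriales	order	2.0
Verrucomicrobiales	order	1.5
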