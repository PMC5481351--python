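taxon_8880	tii_8880	taxon_6666	tii_6666	printed_decrease	note
Acidobacterium capsulatum	339984.56	Acanthamoeba polyphaga mimivirus	176059.76		replaced
Archaeoglobus fulgidus	275171.68	Archaeoglobus fulgidus	276206.40	-0.004	unit_inconsistency
Arcobacter butzleri	389177.39	Arcobacter butzleri	260465.25	33.07
Burkholderia sp.	384956.57	Burkholderia sp.	202131.54	47.49
Chlorobium phaeobacteroides	348612.99	Bovine coronavirus	139006.79		replaced
Daphnia pulex	296748.86	Daphnia pulex	51657.62	82.59
Emiliania huxleyi	252024.48	Emiliania huxleyi	86941.27	65.50
Gluconacetobacter diazotrophicus	351756.39	Gluconacetobacter diazotrophicus	208054.12	40.85
Gramella forsetii	367648.99	Gramella forsetii	172381.65	53.11
Haloarcula marismortui	245672.98	Haloarcula marismortui	227995.40	7.20
Haloquadratum walsbyi	244554.08	Haloquadratum walsbyi	227292.68	7.06
Lottia gigantea	244638.31	Lottia gigantea	51716.23	78.86
Methanoculleus marisnigri	216223.26	Methanoculleus marisnigri	193300.26	10.60
Methanosarcina mazei	218019.48	Methanosarcina mazei	194245.12	10.90
Mus musculus	221980.99	Megavirus chilensis	176092.12		replaced
Nectria haematococca	278079.67	Nectria haematococca	115236.83	58.56
Pan troglodytes	239186.33	Pandoravirus dulcis	145974.04		replaced
Pyrococcus horikoshii	151131.73	Pandoravirus salinus	143402.03		replaced
Roseiflexus castenholzii	454093.65	Roseiflexus castenholzii	216056.64	52.42
Sorghum bicolor	271355.69	Sorghum bicolor	102020.45	62.40
Sulfolobus tokodaii	208389.88	Sulfolobus tokodaii	365974.42	-75.62
Thermococcus kodakarensis	151131.73	Sweet potato chlorotic stunt virus	139006.79		replaced
Thermosipho melanesiensis	350181.51	Thermosipho melanesiensis	308662.81	11.86
Xenopus laevis	254966.77	Xenopus laevis	63294.76	75.18
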