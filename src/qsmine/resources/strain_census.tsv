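# qsmine packaged census of the acidophile study cohort: genome counts per genus.
# Columns: genus	n_genomes
Acidithiobacillus	41
Leptospirillum	12
Sulfobacillus	17
Acidiphilium	13
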