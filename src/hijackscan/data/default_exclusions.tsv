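kind	value	note
family_id	PF01353	green fluorescent protein, a cloning-vector contamination
pattern	polymerase	replication enzymes exchanged among many lineages
pattern	exonuclease	replication enzymes
pattern	endonuclease	replication enzymes
pattern	helicase	replication enzymes
pattern	tRNA[ _-]?synt	tRNA synthetases
pattern	primase	replication enzymes
pattern	green[ _-]?fluorescent	GFP by name
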