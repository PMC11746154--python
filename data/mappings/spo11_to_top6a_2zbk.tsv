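# Residue mapping between the catalytic subunit of the DNA-bound core
# complex (PDB 8URQ) and the cognate domains of the two Top6A protomers in
# the S. shibatae Topo VI holoenzyme (PDB 2ZBK), for template-guided dimer
# assembly.  One row pairs one complex residue with one template residue;
# C-alpha atoms are used for alignment.
#
# The WH-side rows must cover catalytic-subunit residues <= 172 and the
# Toprim-side rows residues >= 173 (the domain split is between 172 and
# 173).  This shipped table is an editable seed and must be completed by
# structure-guided C-alpha pairing against the deposited coordinates (see
# docs/methods.md); only the catalytic-tyrosine and metal-triad anchor
# correspondences are prefilled, and the template chain ids below must be
# checked against the Top6A protomer chains of the deposited 2ZBK entry.
complex_chain	complex_seq_id	template_chain	template_seq_id
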