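# Gene-symbol prefixes excluded from hub calls by default.
# Cytosolic and mitochondrial ribosomal proteins dominate interactome degree
# for technical reasons and are removed from candidate hub genes.
RPL
RPS
MRPL
MRPS
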