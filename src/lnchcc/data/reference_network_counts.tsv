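key	value
n_edges	249
n_positive_edges	146
n_lnc_nodes	103
n_mrna_nodes	131
n_de_lnc	214
n_de_mrna	338
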