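name,symbol,source
female_biased_immune,DDX3X,X-linked immune escape genes with confirmed female-biased airway expression
female_biased_immune,PRKX,X-linked immune escape genes with confirmed female-biased airway expression
female_biased_immune,TXLNG,X-linked immune escape genes with confirmed female-biased airway expression
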