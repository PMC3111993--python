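# pattern	replacement
\bdomain protein domain protein\b	domain protein
\bfamily protein family protein\b	family protein
\bprotein domain protein\b	domain protein
\bprotein family protein\b	family protein
\bprotein protein\b	protein
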