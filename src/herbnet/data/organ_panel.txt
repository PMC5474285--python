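# Immunity-related organ/tissue panel used for above-average expression
# calls, one tissue label per line.
BDCA4+ dendritic cells
Bone marrow
CD14+ monocytes
CD19+ B cells
CD33+ myeloid
CD34+ hematopoietic stem cells
CD4+ T cells
CD56+ NK cells
CD8+ T cells
Colon
Colorectal adenocarcinoma
Liver
Lymph nodes
Lymphoblasts
Small intestine
Smooth muscle
Thymus
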