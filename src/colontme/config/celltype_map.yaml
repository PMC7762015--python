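# Mapping from deconvolution cell types (CIBERSORTx-style 22-type header)
# to model variables.  The naive-macrophage entry feeds the capacity
# M0 = MN + M rather than a dynamic variable.  Types not listed anywhere
# still count toward the immune-ratio normalization but carry no model
# variable.  Edit this file (data, not code) to change the mapping.
version: 1
variables:
  TN: ["T cells CD4 naive"]
  Th: ["T cells CD4 memory activated", "T cells follicular helper"]
  TC: ["T cells CD8", "NK cells activated"]
  Tr: ["T cells regulatory (Tregs)"]
  DN: ["Dendritic cells resting"]
  D: ["Dendritic cells activated"]
  M: ["Macrophages M1", "Macrophages M2"]
naive_macrophages: ["Macrophages M0"]
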