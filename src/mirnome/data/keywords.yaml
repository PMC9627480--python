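# Category -> keyword families used to classify free-text KO-phenotype terms.
# Matching is case-insensitive substring; the first listed category with a
# matching keyword wins. Explicit per-record categories always override.
reproductive_system:
  - testis
  - epididymis
  - uterus
  - ovary
  - infertility
  - seminal
  - vagina
  - oviduct
  - sperm
  - estrous
embryo:
  - embryo
  - embryonic
  - placenta
  - neural tube
  - yolk sac
  - umbilical
  - implantation
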