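name: human_v1
focal_species: Homo sapiens
# Age classes ordered oldest -> youngest (index 1 = oldest).
classes:
  - Bilateria
  - Coelomata
  - Chordata
  - Euteleostomi
  - Tetrapoda
  - Amniota
  - Mammalia
  - Theria
  - Eutheria
  - Simiiformes
  - Catarrhini
  - Hominidae
  - HomoPanGorilla
  - Homo sapiens
# Taxa collapsed onto an existing class before lookup.
collapse_aliases:
  Euarchontoglires: Eutheria
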