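name: mouse_v1
focal_species: Mus musculus
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
  - Glires
  - Rodentia
  - Murinae
  - Mus musculus
collapse_aliases:
  Euarchontoglires: Eutheria
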