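# Synonym table mapping annotation dialects to canonical protein-coding gene
# names of the vertebrate mitogenome. Keys are canonical names; values list
# raw labels (case-insensitive; spaces/hyphens/underscores ignored on lookup).
# Edit or extend to accommodate further GenBank annotation styles.
NAD1:
  - ND1
  - NADH1
  - NADH dehydrogenase subunit 1
  - NADH dehydrogenase subunit I
NAD2:
  - ND2
  - NADH2
  - NADH dehydrogenase subunit 2
  - NADH dehydrogenase subunit II
NAD3:
  - ND3
  - NADH3
  - NADH dehydrogenase subunit 3
NAD4:
  - ND4
  - NADH4
  - NADH dehydrogenase subunit 4
NAD4L:
  - ND4L
  - NADH4L
  - NADH dehydrogenase subunit 4L
NAD5:
  - ND5
  - NADH5
  - NADH dehydrogenase subunit 5
NAD6:
  - ND6
  - NADH6
  - NADH dehydrogenase subunit 6
COI:
  - COX1
  - CO1
  - COXI
  - cytochrome c oxidase subunit 1
  - cytochrome c oxidase subunit I
  - cytochrome oxidase subunit 1
COII:
  - COX2
  - CO2
  - COXII
  - cytochrome c oxidase subunit 2
  - cytochrome c oxidase subunit II
  - cytochrome oxidase subunit 2
COIII:
  - COX3
  - CO3
  - COXIII
  - cytochrome c oxidase subunit 3
  - cytochrome c oxidase subunit III
  - cytochrome oxidase subunit 3
ATP6:
  - ATPase6
  - ATPase 6
  - ATP synthase 6
  - ATP synthase F0 subunit 6
  - ATP synthase subunit 6
ATP8:
  - ATPase8
  - ATPase 8
  - ATP synthase 8
  - ATP synthase F0 subunit 8
  - ATP synthase subunit 8
CYTB:
  - COB
  - CYB
  - cyt b
  - cytb
  - cytochrome b
  - cytochrome-b
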