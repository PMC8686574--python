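06ad02caf97d53b8e620a29774599ff31292d0b2d82fdb5e1b713f3d71d0e09a  table1_validated_parents.tsv
7aedd137531522fc08426083c49240da648e1031f61af5ff7d4db0fc75f232a8  table2_enrolled_parents.tsv
d76a7fbe6ed55f8f4279b5654801b574b3e0aa331f761cc96775dd245af3c6ff  table3_tissue_panels.tsv
5b51d15919394875c868b3e1a7a0e3fa4572b5b1390602c78b8ee23d656ec8dc  cohort_counts.json
19e88e3efc492a50c91225d6e2175410059708986fcad73af3fd3b4988e7c93d  germ_layers.tsv
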