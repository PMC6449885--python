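{
  "config": null,
  "files": {
    "associations.tsv": "32ce3ebc7e6d259725e24df5270fad87bf98e17ca0515a9cedb428267e59a0db",
    "disease_genes.tsv": "1839d48a59228a6ebd581a61f0cc7ce7f93e78203acb985573527ccbea12b0fe",
    "family.tsv": "d8d96adcac69b4d417f101d872cb0308c33b72e6712fea195e03d7f68f18bc88",
    "mesh.tsv": "1dc4d025c81a7111c25fad5b2daa9da54198939e8c6e24e0323c18b6f7863e31",
    "mirna_targets.tsv": "201245a02f2cfcc1c0374a62982fdd07d5b9cc8d509ffc449f025270683e2882",
    "mirnas.gff3": "40e128db38ab4cb845505ce0917549c8282807336eaef66d79109f839b305de2"
  },
  "seed": null
}
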