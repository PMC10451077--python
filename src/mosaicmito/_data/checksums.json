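{
  "haplogroup_markers_mini.tsv": "15974388cb6848c5be72cb9b4e54fca4b54aa05bab690453f1b4b5d0075f950e",
  "rcrs_features.gff3": "44d90e099e5e17c0a53f7acfe9c64e4804f8b3b1872c6046aa482e83b421c864",
  "rcrs_synthetic.fasta": "4b414bccf81d6fad819ed0f61ee9368b9591d41283f90fa0301c5597f80ad40f",
  "table1_embryos.csv": "8dbcef42e759989853c4507fff5026b9ec943f5f4a08e3944c5f9aaf1ce633a6",
  "trna_pathogenic_mini.tsv": "712595411ba04cbbeb4e83fda2e64ada7fd8b0f8637d02347bee149853ee9e66"
}
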