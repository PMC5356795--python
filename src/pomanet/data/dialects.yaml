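# Column-mapping dialects for the miRNA-target databases commonly merged
# into an integrated regulatory network. Keys: "mirna"/"gene" name a header
# column (string) or a 0-based position (int, with header: false).
# The databases themselves are not bundled; these mappings describe the
# export formats their download pages produce.
mirecords:
  mirna: miRNA_mature_ID
  gene: Target gene_name
  header: true
tarbase:
  mirna: mirna
  gene: geneName
  header: true
mir2disease:
  mirna: 0
  gene: 1
  header: false
mirtarbase:
  mirna: miRNA
  gene: Target Gene
  header: true
hoctar:
  mirna: 0
  gene: 1
  header: false
exprtargetdb:
  mirna: miRNA
  gene: gene_symbol
  header: true
starbase:
  mirna: miRNAname
  gene: geneName
  header: true
default:
  mirna: mirna
  gene: gene
  header: true
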