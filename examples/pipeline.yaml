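# Demo pipeline: simulate an extreme-bulk panel over the 13-gene region
# fixture, then rank the genes by variation-index contrast.
seed: 1
stages:
  - stage: simulate
    kind: bulks
    out: simdata
  - stage: bulkscan
    vcf: simdata/calls.vcf
    bulks: simdata/bulks.yaml
    gff: simdata/genes.gff3
    threshold: 0.3
    out: ranking.tsv
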