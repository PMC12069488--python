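# Minimal end-to-end configuration: simulate a reference and reads, then
# classify them. Later stages (filter, normalize, signature, ...) consume
# the classify outputs; see README.md.
seed: 11

simulate:
  n_hairpins: 8
  library_size: 20000
  n_samples: 3
  n_datasets: 2

classify:
  hairpin_fasta: out/hairpins.fasta
  annotation: out/matures.tsv
  reads:
    ds1: out/reads.ds1.tsv
    ds2: out/reads.ds2.tsv
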