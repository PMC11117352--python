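# Bundled data

- `tetraodontiformes_funnel.tsv`, `tetraodontiformes_elements.tsv`,
  `tetraodontiformes_distribution.tsv` — literature-derived reference
  tabulations of LTR retrotransposon surveys across ten tetraodontiform
  genomes (mining funnel counts per genome; per-element classification and
  geometry; family-by-species distribution). They are consumed verbatim by
  the reporting aggregations and by regression tests; no reconciliation
  between the funnel's 819 full-length sequences and the 443 tabulated
  element copies is attempted (the source tables leave it open). See
  docs/methods.md.
- `domain_profiles.synthetic.tsv` — position-specific score models (bits)
  for GAG/POL/RT/RH/INT/ENV. *Synthetic*: built from fixed consensus
  peptides shared with the synthetic-genome generator, not distilled from
  curated seed alignments.
- `reference_panel.synthetic.fasta` — RT-bearing polyprotein per family,
  tagged `family=` / `superfamily=`. *Synthetic*: deterministic
  constructions matching the generator's family templates.
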