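# Input data

Place the canonical UniProt FASTA files here to run the published
phytochrome sequence comparison:

- `phya_p_sativum.fasta` — P. sativum phytochrome A (UniProt P15001)
- `phyb_a_thaliana.fasta` — A. thaliana phytochrome B (UniProt P14713)

The sequences are not redistributed with this repository.
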