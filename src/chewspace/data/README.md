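Reference-entry cache.

`chewspace fetch-reference-data` downloads the CheW case-study inputs here:
P0A964.fasta, Q56311.fasta, 2HO9.pdb, 1K0S.pdb. They are not redistributed
with the package.
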