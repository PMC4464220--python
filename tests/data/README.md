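# Test data

`1y26.pdb` — RCSB entry 1Y26 (adenine riboswitch aptamer crystal
structure), plain PDB format. Not bundled; download it with

    curl -o tests/data/1y26.pdb https://files.rcsb.org/download/1Y26.pdb

It is required only by the crystal-structure acceptance tests in
`tests/test_acceptance.py::TestCriterion2CrystalStructure`; every other
test generates its inputs programmatically.
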