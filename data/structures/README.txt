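Place the deposited crystal/NMR structures here for the structure-anchored
validation tests: 1j1e.pdb, 1ytz.pdb, 1yv0.pdb (and optionally 2jpw.pdb).
`python scripts/fetch_structures.py` downloads them when network access is
available. Without these files, tests/test_acceptance.py reports exactly
which entries are missing; all other tests are unaffected.
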