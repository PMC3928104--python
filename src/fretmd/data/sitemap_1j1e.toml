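# Default site map for the Ca2+-saturated cardiac troponin core domain crystal
# structure (PDB 1J1E), author residue numbering.  The deposited entry contains
# more than one copy of the complex; per-copy chain assignments below follow
# chain order in the file.  Verify against your local copy (chain ids are
# listed in the file header) and override as needed.

[copies.1]
cTnC = "A"
cTnT = "B"
cTnI = "C"

[copies.2]
cTnC = "D"
cTnT = "E"
cTnI = "F"

[copies.3]
cTnC = "G"
cTnT = "H"
cTnI = "I"

[offsets]
cTnC = 0
cTnT = 0
cTnI = 0
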