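# Ligand structure fixtures

Five SDF (V2000) files for the compounds analysed by the package's
similarity module:

| file | compound | formula |
|---|---|---|
| `pomolic_acid.sdf` | pomolic acid (3β,19α-dihydroxyurs-12-en-28-oic acid) | C30H48O4 |
| `hederagenin.sdf` | hederagenin (3β,23-dihydroxyolean-12-en-28-oic acid) | C30H48O4 |
| `caulophyllogenin.sdf` | caulophyllogenin (3β,16α,23-trihydroxyolean-12-en-28-oic acid) | C30H48O5 |
| `betulinic_acid.sdf` | betulinic acid (3β-hydroxylup-20(29)-en-28-oic acid) | C30H48O3 |
| `rosiglitazone.sdf` | rosiglitazone (thiazolidinedione reference agonist) | C18H19N3O3S |

Construction: each file was generated from the compound's constitutional
SMILES (standard literature connectivity; stereocentres omitted, since the
circular fingerprints ignore chirality) with RDKit 2D coordinate
generation, kekulised V2000 output. Molecular formulas were validated
against the values above at generation time.
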