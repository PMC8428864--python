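# External inputs (not redistributed)

The integration checks in `tests/test_acceptance.py` look here for inputs
that cannot ship with the package:

| file | content |
| --- | --- |
| `6uzv.cif` | deposited trimeric PSI model used as wild-type *Synechocystis* (wwPDB 6UZV) |
| `6vpv.cif` | deposited trimeric PSI model of *C. aponinum* (wwPDB 6VPV) |
| `6uzv_labels.yaml` | pigment label map for 6UZV (`B18`, `B19`, `B40`, `B7`, `I-W20`, …) filled from the deposited file |
| `6vpv_labels.yaml` | pigment label map for 6VPV |
| `absorbance_caponinum.csv` | purified-trimer absorbance, *C. aponinum* (two columns: nm, intensity) |
| `absorbance_synechocystis.csv` | purified-trimer absorbance, *Synechocystis* |
| `absorbance_redc.csv` | purified-trimer absorbance, chimeric *Red_c* strain |
| `absorbance_wt_synechocystis.csv` | purified-trimer absorbance, wild-type *Synechocystis* |

Coordinate files come from the wwPDB; absorbance curves from the published
source data accompanying the study of these complexes. Label maps use the
YAML schema of `psispec.structure_io.PigmentLabelMap` (the residue numbers
behind canonical pigment labels are a property of each deposited model and
must be read off the file, not assumed).
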