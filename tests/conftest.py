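from pathlib import Path

import numpy as np
import pytest

#: Directory for optional real-data inputs (deposited coordinate files,
#: published source-data spectra). Not distributed with the package.
EXTERNAL_DATA = Path(__file__).resolve().parent.parent / "data" / "external"

PDB_3ATOMS = """\
CRYST1    1.000    1.000    1.000  90.00  90.00  90.00 P 1
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 10.00           C
ATOM      3  C   ALA A   1      12.773   7.060  -4.915  1.00 10.00           C
END
"""

PDB_ALTLOC = """\
CRYST1    1.000    1.000    1.000  90.00  90.00  90.00 P 1
ATOM      1  N  AALA A   1      11.104   6.134  -6.504  0.60 10.00           N
ATOM      2  N  BALA A   1      99.000   6.134  -6.504  0.40 10.00           N
ATOM      3  CA AALA A   1      11.639   6.071  -5.147  0.50 10.00           C
ATOM      4  CA BALA A   1      88.000   6.071  -5.147  0.50 10.00           C
END
"""


@pytest.fixture
def pdb_3atoms(tmp_path):
    p = tmp_path / "three_atoms.pdb"
    p.write_text(PDB_3ATOMS)
    return p


@pytest.fixture
def pdb_altloc(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(PDB_ALTLOC)
    return p


def moment_fwhm(x, y):
    """FWHM from the intensity-weighted second moment (Gaussian assumption)."""
    w = y / y.sum()
    m = (x * w).sum()
    return 2.0 * np.sqrt(2.0 * np.log(2.0)) * np.sqrt(((x - m) ** 2 * w).sum())


def interp_fwhm(x, y):
    """FWHM from linearly interpolated half-maximum crossings."""
    half = y.max() / 2.0
    i = int(np.argmax(y))
    left = np.interp(half, y[: i + 1], x[: i + 1])
    right = np.interp(half, y[i:][::-1], x[i:][::-1])
    return right - left
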