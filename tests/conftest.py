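import numpy as np
import pytest

from lumiqc.plate import ROWS, N_COLS


def matrix_text(values, delimiter="\t"):
    """Render a 16x24 array as the plate-reader matrix dialect."""
    values = np.asarray(values)
    lines = [delimiter.join([""] + [str(i) for i in range(1, N_COLS + 1)])]
    for r, row in zip(ROWS, values):
        lines.append(delimiter.join([r] + [repr(float(v)) for v in row]))
    return "\n".join(lines) + "\n"


@pytest.fixture
def uniform_plate_text():
    return matrix_text(np.zeros((16, 24)))


@pytest.fixture
def full_platemap_csv():
    """384-well map: column 23 negative, 24 positive, the rest samples."""
    lines = ["well,role,compound_id,concentration,conc_unit"]
    for r in ROWS:
        for c in range(1, N_COLS + 1):
            if c == 23:
                lines.append(f"{r}{c},negative_control,,,")
            elif c == 24:
                lines.append(f"{r}{c},positive_control,,,")
            else:
                lines.append(f"{r}{c},sample,Ag,1,mM")
    return "\n".join(lines) + "\n"
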