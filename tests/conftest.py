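import base64

import numpy as np
import pytest

from lissoir.simulate import fixtures


@pytest.fixture(scope="session")
def fx():
    """Packaged tables: assemblages, body masses, markers, proteins."""
    return fixtures()


def write_minimal_mzml(path, mz, intensity, compress=False):
    """Write a single-spectrum mzML file (64-bit LE, zlib or none)."""
    import zlib

    def encode(arr):
        raw = np.asarray(arr, dtype="<f8").tobytes()
        if compress:
            raw = zlib.compress(raw)
        return base64.b64encode(raw).decode()

    comp_acc, comp_name = (
        ("MS:1000574", "zlib compression") if compress else ("MS:1000576", "no compression")
    )

    def array_block(acc, name, arr):
        return (
            "<binaryDataArray>"
            '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>'
            f'<cvParam cvRef="MS" accession="{comp_acc}" name="{comp_name}"/>'
            f'<cvParam cvRef="MS" accession="{acc}" name="{name}"/>'
            f"<binary>{encode(arr)}</binary>"
            "</binaryDataArray>"
        )

    xml = (
        '<?xml version="1.0" encoding="utf-8"?>'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">'
        '<run id="run1"><spectrumList count="1">'
        f'<spectrum index="0" id="scan=1" defaultArrayLength="{len(mz)}">'
        '<binaryDataArrayList count="2">'
        + array_block("MS:1000514", "m/z array", mz)
        + array_block("MS:1000515", "intensity array", intensity)
        + "</binaryDataArrayList></spectrum></spectrumList></run></mzML>"
    )
    path.write_text(xml)
    return path
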