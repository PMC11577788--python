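import pytest

from barcodeq import parse_template
from barcodeq import reference as ref
from barcodeq.codon import STANDARD_TABLE


@pytest.fixture(scope="session")
def template():
    return parse_template(ref.BARCODE_TEMPLATE_OLIGO)


@pytest.fixture(scope="session")
def whitelist():
    return ref.strain_whitelist()


@pytest.fixture(scope="session")
def table():
    return STANDARD_TABLE
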