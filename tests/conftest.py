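import pytest

from bfcea import default_parameters


@pytest.fixture
def params():
    return default_parameters()


# Published transition tables, frozen here independently of the package's
# built-in defaults so the tests assert against the printed values rather
# than against whatever the code returns.

PRINTED_FEEDING = {
    "control": {
        1: (0.67, 0.33, 0.82, 0.18),
        2: (0.73, 0.27, 0.76, 0.24),
        3: (0.74, 0.26, 0.72, 0.28),
        4: (0.75, 0.25, 0.70, 0.30),
        5: (0.76, 0.24, 0.68, 0.32),
        6: (0.77, 0.23, 0.66, 0.34),
    },
    "intervention": {
        1: (0.81, 0.19, 0.93, 0.07),
        2: (0.89, 0.11, 0.85, 0.15),
        3: (0.91, 0.09, 0.79, 0.21),
        4: (0.92, 0.08, 0.75, 0.25),
        5: (0.92, 0.08, 0.71, 0.29),
        6: (0.93, 0.07, 0.68, 0.32),
    },
}

PRINTED_HEALTH = {
    ("intervention", "EBF/PBF"): (0.08, 0.88, 0.12, 0.92),
    ("intervention", "MF/RF"): (0.07, 0.86, 0.14, 0.93),
    ("control", "EBF/PBF"): (0.06, 0.64, 0.36, 0.94),
    ("control", "MF/RF"): (0.10, 0.71, 0.29, 0.90),
}
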