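import numpy as np
import pandas as pd
import pytest

from core_responder.io_model import CountTable, StudyDesign, TaxonomyTable


@pytest.fixture
def small_table():
    counts = np.array(
        [
            [10, 5, 0, 1],
            [8, 0, 2, 1],
            [12, 6, 0, 2],
            [9, 4, 3, 0],
        ]
    )
    return CountTable([f"s{i}" for i in range(1, 5)], [f"t{j}" for j in range(1, 5)], counts)


@pytest.fixture
def small_design():
    rows = []
    ids = []
    for eco, tol in (("E01", "tolerant"), ("E02", "sensitive")):
        for treatment in ("control", "drought"):
            for rep in (1, 2):
                ids.append(f"{eco}.{treatment}.r{rep}")
                rows.append(
                    {
                        "ecotype": eco,
                        "treatment": treatment,
                        "tolerance_class": tol,
                        "replicate": rep,
                    }
                )
    return StudyDesign(pd.DataFrame(rows, index=ids))


@pytest.fixture
def hand_taxonomy():
    frame = pd.DataFrame(
        {
            "kingdom": ["Bacteria"] * 4,
            "phylum": ["P1"] * 4,
            "class": ["C1"] * 4,
            "order": ["O1"] * 4,
            "family": ["Oxalobacteraceae", "Oxalobacteraceae", "F2", "F2"],
            "genus": ["Massilia", "Massilia", "", ""],
            "species": ["", "", "", ""],
        },
        index=["t1", "t2", "t3", "t4"],
    )
    return TaxonomyTable(frame)
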