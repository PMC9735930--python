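import numpy as np
import pytest

from liekit.datasets import LIEDataset, LIEEntry, LigandEntry
from liekit.energies import EnsembleEstimate
from liekit.io import load_docking_table, load_lie_reference, load_reference_dataset


@pytest.fixture(scope="session")
def reference_dataset() -> LIEDataset:
    """The packaged 13-analog averages joined with IC50 and docking records."""
    return load_reference_dataset()


@pytest.fixture(scope="session")
def reference_table():
    """Packaged averages plus the reported free-energy reference columns."""
    return load_lie_reference()


@pytest.fixture(scope="session")
def docking_table():
    """The packaged 16-analog docking-score / IC50 table."""
    return load_docking_table()


def make_entry(
    ligand_id: str,
    d_vdw: float,
    d_ele: float,
    ic50_um: float | None = None,
    free_vdw: float = -28.0,
    free_ele: float = -30.0,
) -> LIEEntry:
    """Minimal dataset entry with prescribed bound-minus-free differences."""
    return LIEEntry(
        ligand=LigandEntry(ligand_id=ligand_id, ic50_um=ic50_um),
        free_vdw=EnsembleEstimate(mean=free_vdw),
        free_ele=EnsembleEstimate(mean=free_ele),
        bound_vdw=EnsembleEstimate(mean=free_vdw + d_vdw),
        bound_ele=EnsembleEstimate(mean=free_ele + d_ele),
    )
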