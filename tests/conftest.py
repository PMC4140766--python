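import numpy as np
import pytest

from adenoma_prs.core_io import GenotypeMatrix, SnpDef, SnpPanel


@pytest.fixture
def toy_panel() -> SnpPanel:
    """Two-SNP panel with simple weights and known control frequencies."""
    return SnpPanel(
        (
            SnpDef("rs1", "1", 1000, "A", "G", "G", 0.2, 0.5),
            SnpDef("rs2", "2", 2000, "C", "T", "T", 0.5, 0.3),
        )
    )


@pytest.fixture
def toy_matrix(toy_panel) -> GenotypeMatrix:
    return GenotypeMatrix(
        ["s1", "s2", "s3"],
        toy_panel.rsids,
        np.array([[0, 0], [1, 2], [2, -1]], dtype=np.int8),
    )


def make_matrix(dosage, prefix="s", rsids=None) -> GenotypeMatrix:
    dosage = np.asarray(dosage, dtype=np.int8)
    rsids = rsids or [f"rs{j}" for j in range(dosage.shape[1])]
    return GenotypeMatrix([f"{prefix}{i}" for i in range(dosage.shape[0])], rsids, dosage)
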