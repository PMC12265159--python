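import numpy as np
import pytest

from fecalsig.markers import Marker, MarkerPanel
from fecalsig.synthio import (
    CohortConfig,
    MixtureSpec,
    PlantedEffect,
    generate_marker_panel,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_panel() -> MarkerPanel:
    """Three cell types, one 150-bp marker each, five CpGs."""
    return generate_marker_panel(
        3, 1, 150, 5, seed=11, cell_type_names=["neutrophil", "colon", "T_cell"]
    )


@pytest.fixture(scope="session")
def full_panel() -> MarkerPanel:
    """Six cell types x two markers, the default panel shape."""
    return generate_marker_panel(6, 2, 150, 5, seed=13)


@pytest.fixture(scope="session")
def tiny_marker() -> Marker:
    """Hand-built marker with known CpG offsets for exact-call tests."""
    #          0123456789...
    seq = "ATCGATTTCGAATCGACCTTACGTT"
    return Marker("m0", "neutrophil", seq, (2, 8, 13, 21))


@pytest.fixture(scope="session")
def ecology_cohort():
    """Cohort with planted categories; no bisulfite reads (species-only)."""
    cfg = CohortConfig(
        n_per_group={"Control": 25, "CD": 25, "UC": 25},
        n_species_pool=200,
        reads_per_marker=0,
        planted_categories={
            "Species_0000": PlantedEffect("IBD_LOST", 0.05),
            "Species_0001": PlantedEffect("CD_EXPANDED", 20.0),
        },
        seed=21,
    )
    return simulate_cohort(cfg)
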