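import numpy as np
import pytest

from bfgscreen.design import Barcode, CountMatrix, ScreenDesign, Strain


def _bc(rng: np.random.Generator, locus: str, ident: str) -> Barcode:
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=25))
    return Barcode(ident, seq, locus)


def make_design(n_baits: int = 2, n_preys: int = 2, seed: int = 0, **kwargs) -> ScreenDesign:
    """Small random screen design; one strain per ORF."""
    rng = np.random.default_rng(seed)
    baits = [
        Strain(
            f"b{i}", "bait", f"BORF{i}",
            _bc(rng, "bait-BC1", f"b{i}-1"), _bc(rng, "bait-BC2", f"b{i}-2"),
        )
        for i in range(n_baits)
    ]
    preys = [
        Strain(
            f"p{j}", "prey", f"PORF{j}",
            _bc(rng, "prey-BC1", f"p{j}-1"), _bc(rng, "prey-BC2", f"p{j}-2"),
        )
        for j in range(n_preys)
    ]
    return ScreenDesign(baits=baits, preys=preys, **kwargs)


def make_counts(design: ScreenDesign, counts, condition="-His", fusion_type="BC1BC1",
                replicate="r1", unmatched=0) -> CountMatrix:
    return CountMatrix(
        axis_baits=design.bait_ids,
        axis_preys=design.prey_ids,
        counts=np.asarray(counts),
        condition=condition,
        fusion_type=fusion_type,
        replicate=replicate,
        unmatched=unmatched,
    )


@pytest.fixture
def design2x2():
    return make_design(2, 2, seed=1)


@pytest.fixture(scope="session")
def small_screen():
    """One small simulated screen shared across tests (seeded, deterministic)."""
    from bfgscreen.simulator import SimulationParams, simulate_screen

    params = SimulationParams(
        n_bait_orfs=20,
        n_prey_orfs=20,
        mating_cells=400_000,
        plated_cells=2_000_000,
        extraction_molecules=200_000,
        pcr_template_molecules=100_000,
        read_depth=100_000,
        seed=42,
    )
    counts, ledger = simulate_screen(params)
    return counts, ledger
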