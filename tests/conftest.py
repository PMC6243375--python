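import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oglyco.digestion import PeptideEntry, ProteinRecord
from oglyco.search import GlycoPSM, ModifiedPeptide
from oglyco.masses import GlycanComposition, peptide_mass

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_psm(
    sequence: str = "TKLSPNR",
    scan_id: str = "s1",
    score: float = 10.0,
    is_decoy: bool = False,
    glycan: GlycanComposition | None = GlycanComposition(hex=1, hexnac=1),
    oxonium_passed: bool = True,
    q_value: float = 0.0,
    run: str = "run1",
    parents: set | None = None,
) -> GlycoPSM:
    """Assemble a minimal GlycoPSM for unit tests."""
    entry = PeptideEntry(
        sequence=sequence,
        parents=parents or {("P1", 1)},
        tryptic_mc=0,
        operator_mc=0,
    )
    placements = ((1, glycan),) if glycan is not None else ()
    peptide = ModifiedPeptide(
        entry=entry,
        placements=placements,
        total_mass=peptide_mass(sequence, placements),
    )
    return GlycoPSM(
        scan_id=scan_id,
        source_run=run,
        peptide=peptide,
        charge=2,
        precursor_mz=500.0,
        score=score,
        is_decoy=is_decoy,
        oxonium_passed=oxonium_passed,
        q_value=q_value,
    )


@pytest.fixture
def psm_factory():
    return make_psm
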