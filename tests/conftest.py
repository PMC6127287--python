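import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from primerscope.fixtures import CladeSpec, generate_clade
from primerscope.msa import align_progressive
from primerscope.primer_design import DesignConstraints, design_primers

PLANTED_FWD = "GCTCAGGAYGAACGCYGG"
PLANTED_REV = "CACCGCTACACATGRADTTC"


@pytest.fixture(scope="session")
def clade():
    """Default synthetic clade: 20 targets, 5 outgroups, 750 bp product."""
    return generate_clade(CladeSpec(seed=1))


@pytest.fixture(scope="session")
def clade_alignment(clade):
    return align_progressive(clade.targets)


@pytest.fixture(scope="session")
def designed(clade, clade_alignment):
    """(candidates, pairs) from a full design pass on the synthetic clade."""
    return design_primers(clade_alignment, DesignConstraints(),
                          reference_id=clade.targets[0].id)


@pytest.fixture(scope="session")
def planted_pair(designed):
    _, pairs = designed
    matches = [p for p in pairs
               if p.forward.sequence == PLANTED_FWD and p.reverse.sequence == PLANTED_REV]
    assert matches, "design did not recover the planted pair"
    return matches[0]
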