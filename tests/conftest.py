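import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chronobef.bef_stats import bef_per_plot
from chronobef.community import diversity_profile
from chronobef.functions import multifunctionality_table
from chronobef.synthetic_data import GroupDesign, StudyDesign, generate_study

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def small_groups() -> dict[str, GroupDesign]:
    """Reduced OTU pools / depths for fast tests; the group structure and
    depth ordering (invertebrates < protists < fungi < bacteria) is kept."""
    return {
        "invertebrates": GroupDesign(40, 50),
        "protists": GroupDesign(60, 80),
        "fungi": GroupDesign(80, 100),
        "bacteria": GroupDesign(100, 150),
    }


def tiny_design(seed: int = 3, **kw) -> StudyDesign:
    """4 chronosequences, 10 plots, small pools."""
    base = dict(
        n_chronosequences=4,
        plots_per_chronosequence=[3, 3, 2, 2],
        organism_groups=small_groups(),
        seed=seed,
    )
    base.update(kw)
    return StudyDesign(**base)


def one_family_bef(study, seed: int):
    """Per-plot BEF records for the (multidiversity, MF_avg) family only —
    the light path used by trend and recovery tests."""
    div = diversity_profile(study.otu_tables, seed=seed)
    mf = multifunctionality_table(study.functions)
    bef = bef_per_plot(div[["multidiversity"]], mf[["MF_avg"]], None, study.samples)
    return bef, div, mf


@pytest.fixture(scope="session")
def default_study():
    """The reference design: 16 chronosequences, 87 plots, 435 samples."""
    return generate_study(StudyDesign(seed=1))


@pytest.fixture(scope="session")
def default_diversity(default_study):
    return diversity_profile(default_study.otu_tables, seed=1)


@pytest.fixture(scope="session")
def default_mf(default_study):
    return multifunctionality_table(default_study.functions)


@pytest.fixture(scope="session")
def tiny_study():
    return generate_study(tiny_design())


@pytest.fixture
def rng():
    return np.random.default_rng(42)
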