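import numpy as np
import pandas as pd
import pytest

from cardiogrs import default_panel, emulate_study, grs_engine, phenotyping
from cardiogrs.panel_io import SNPDef, SNPPanel


@pytest.fixture(scope="session")
def panel18():
    return default_panel()


@pytest.fixture
def panel3():
    """Explicit three-SNP test panel (risk alleles are configuration)."""
    return SNPPanel(
        (
            SNPDef("rs9939609", "A", "FTO"),
            SNPDef("rs7903146", "T", "TCF7L2"),
            SNPDef("rs17782313", "C", "MC4R"),
        )
    )


@pytest.fixture(scope="session")
def study_cohort():
    """One realization of the default study conditions (n = 4279)."""
    return emulate_study(seed=1)


@pytest.fixture(scope="session")
def scored_study(study_cohort, panel18):
    """Classified + GRS-scored analysis frame for the study cohort."""
    pheno = phenotyping.classify_cohort(study_cohort.phenotypes)
    grs = grs_engine.score_cohort(study_cohort.genotypes, panel18)
    cohort = pheno.join(grs, how="inner")
    cohort["overweight_obese"] = cohort["bmi_class"] == "overweight_obese"
    return cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
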