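import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from rocglm.pipeline import reference_coefficient_sets, load_reference_coefficients

# reproducible property tests: example generation is derandomised
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def reference_sets():
    """Published coefficient sets for the three OCT markers."""
    return reference_coefficient_sets()


@pytest.fixture(scope="session")
def reference_raw():
    return load_reference_coefficients()


def make_eye_rows(n=3, group="glaucoma", **overrides):
    """Plain valid eye-record rows for building toy cohorts."""
    base = dict(
        subject_id=[f"S{i}" for i in range(n)],
        eye=["right"] * n,
        group=[group] * n,
        age=[55.0] * n,
        sex=["female"] * n,
        bcva_logmar=[0.1] * n,
        iop=[14.0] * n,
        spherical_equivalent=[-2.0] * n,
        cylinder=[-0.5] * n,
        axial_length=[24.5] * n,
        md=[-4.0] * n,
        psd=[5.0] * n,
        vfi=[90.0] * n,
        disc_area_measured=[2.0] * n,
        disc_area_corrected=[np.nan] * n,
        rnfl_avg=[80.0] * n,
        gcipl_avg=[75.0] * n,
        gcipl_min=[70.0] * n,
        signal_strength_macula=[8.0] * n,
        signal_strength_disc=[9.0] * n,
        vf_fixation_loss=[5.0] * n,
        vf_false_positive=[2.0] * n,
    )
    base.update(overrides)
    return pd.DataFrame(base)


@pytest.fixture
def toy_frame():
    return make_eye_rows()


@pytest.fixture
def toy_csv(tmp_path, toy_frame):
    path = tmp_path / "cohort.csv"
    toy_frame.to_csv(path, index=False)
    return path
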