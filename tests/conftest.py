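import numpy as np
import pandas as pd
import pytest

import biodosim as bd


@pytest.fixture(scope="session")
def lu177():
    return bd.get_nuclide("lu177")


@pytest.fixture(scope="session")
def cu64():
    return bd.get_nuclide("cu64")


@pytest.fixture(scope="session")
def phantom():
    return bd.read_phantom()


def make_study(nuclide, rows, injected_mbq=3.7, **kwargs):
    """Build a study from (organ, animal_id, time_h, pidg) tuples."""
    samples = pd.DataFrame(rows, columns=["organ", "animal_id", "time_h", "pidg"])
    samples["mass_g"] = 0.2
    return bd.BiodistributionStudy(nuclide=nuclide, injected_mbq=injected_mbq,
                                   samples=samples, **kwargs)


def monoexp_tac(nuclide, a0, lam, times, organ="Liver", **kwargs):
    times = np.asarray(times, dtype=float)
    return bd.TimeActivityCurve(organ=organ, times_h=times,
                                values=a0 * np.exp(-lam * times),
                                nuclide=nuclide, **kwargs)


@pytest.fixture
def reference_study_file(tmp_path):
    """The packaged Lu-177 reference means written out as a study file."""
    study = bd.reference_study("lu177")
    path = tmp_path / "lu177_reference_study.csv"
    bd.write_study(study, path, nuclide_key="lu177")
    return path
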