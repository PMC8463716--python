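import numpy as np
import pytest

import phonesmf as p


@pytest.fixture(scope="session")
def model1():
    """Reference phone model 1 (two hot spots)."""
    return p.REFERENCE_PHONES[0]


@pytest.fixture(scope="session")
def model1_upper_fit(model1):
    """SLC source of the model-1 upper hot spot: r=8 mm, I=17.2 mA, T=8.4 mm."""
    return model1.hotspots[0].slc


@pytest.fixture(scope="session")
def model1_truth(model1):
    """Two-loop ground truth (upper + lower) for synthetic studies."""
    return p.truth_from_record(model1)


@pytest.fixture(scope="session")
def model1_upper_truth(model1):
    """Single-loop ground truth: only the upper hot spot of model 1."""
    h = model1.hotspots[0]
    return p.GroundTruthPhone(
        geometry=model1.geometry,
        loops=(p.LoopSource(h.label, h.x_mm, h.y_mm, h.slc.r_mm, h.slc.I_mA),),
    )


@pytest.fixture(scope="session")
def noiseless_curves():
    """Exact SLC decay curves at the five study heights, one per hot spot."""
    z = np.asarray(p.Z_LEVELS_MM)
    out = {}
    for phone, hs in p.all_hotspots():
        out[(phone.model, hs.label)] = p.DecayCurve(
            z_mm=z, B_uT=p.slc_field(z, hs.slc)
        )
    return out
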