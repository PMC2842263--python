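import numpy as np
import pytest

from hcmstrain.cohort import carrier_group, ground_truth, sample_cohort
from hcmstrain.phantom import ImagingParams, reference_contours, render_tagged_series


@pytest.fixture(scope="session")
def carrier_subject():
    """One representative synthetic carrier."""
    return sample_cohort(carrier_group(), 2, 7)[1]


@pytest.fixture(scope="session")
def noise_free():
    return ImagingParams(snr=np.inf)


@pytest.fixture(scope="session")
def tracked_basal(carrier_subject, noise_free):
    """Rendered noise-free basal tagged series with contours and truth,
    shared across the strain tests (rendering+tracking is the slow part)."""
    series, gt = render_tagged_series(carrier_subject, "basal", noise_free, seed=1)
    contours = reference_contours(series, carrier_subject)
    return series, contours, gt


@pytest.fixture()
def zero_strain_subject(carrier_subject):
    """Same geometry, no deformation."""
    import dataclasses

    return dataclasses.replace(
        carrier_subject,
        peak_scs_pct=np.zeros(16),
        wall_thickening=np.zeros(16),
    )
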