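import numpy as np
import pytest

from famap.calibration import border_margin_mask
from famap.permeability import compute_aif, fit_slope_map, normalize_sequence
from famap.preprocess import flag_noisy_frames
from famap.registration import register_sequence
from famap.synthetic import PhantomSpec, align_truth, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_phantom():
    """One default 128x128, 73-frame phantom with motion and noise."""
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def analyzed_phantom(default_phantom):
    """Full pipeline run on the default phantom, truth aligned to reference."""
    sequence, truth = default_phantom
    flagged = flag_noisy_frames(sequence)
    registration = register_sequence(flagged)
    truth = align_truth(truth, truth.true_shifts[registration.reference_index])
    aif = compute_aif(registration.registered, truth.artery_mask)
    normalized = normalize_sequence(registration.registered, aif)
    slope_map = fit_slope_map(normalized)
    exclusion = border_margin_mask(slope_map.slope.shape) | truth.disc_mask.mask
    return {
        "flagged": flagged,
        "registration": registration,
        "truth": truth,
        "aif": aif,
        "slope_map": slope_map,
        "exclusion": exclusion,
    }
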