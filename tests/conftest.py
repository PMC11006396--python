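import numpy as np
import pytest

from spermscaling import GeneratorConfig, ModelSpec, fit_scaling_model, generate_metabolic_dataset


@pytest.fixture(scope="session")
def default_synth():
    """One default-config synthetic dataset (198 obs, 49 species, seed 1)."""
    return generate_metabolic_dataset(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_fit(default_synth):
    """REML fit of the default dataset with the thermoregulation covariate."""
    return fit_scaling_model(default_synth.dataset, ModelSpec())


def naive_best_window(times, sat, min_size):
    """Brute-force oracle for the local-slope window search: try every
    contiguous window with plain polyfit, same tie rules."""
    n = len(times)
    best_key, best = None, None
    for start in range(n - min_size + 1):
        for stop in range(start + min_size, n + 1):
            t, s = times[start:stop], sat[start:stop]
            slope, intercept = np.polyfit(t, s, 1)
            resid = s - (slope * t + intercept)
            sxx = float(((t - t.mean()) ** 2).sum())
            sigma2 = float(resid @ resid) / (stop - start - 2)
            se = np.sqrt(max(sigma2, 0.0) / sxx)
            crit = se / abs(slope) if slope != 0 else np.inf
            if crit < 1e-12:
                crit = 0.0
            key = (crit, -(stop - start), start)
            if best_key is None or key < best_key:
                best_key = key
                best = (slope * 60.0, se * 60.0, (start, stop))
    return best
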