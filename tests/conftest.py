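import numpy as np
import pandas as pd
import pytest

import tempmort as tm


@pytest.fixture(scope="session")
def small_series() -> tm.DailySeries:
    """A 4-year synthetic city with the default truth."""
    return tm.simulate_city(tm.SynthConfig(n_years=4, seed=7))


@pytest.fixture(scope="session")
def small_results(small_series) -> tm.CityResults:
    """The full two-step analysis on the small fixture."""
    return tm.run_city_analysis(small_series)


def fake_fit(cb: tm.CrossBasis, beta: np.ndarray,
             vcov: np.ndarray | None = None) -> tm.FitResult:
    """A FitResult carrying prescribed cross-basis coefficients."""
    names = cb.column_names
    if vcov is None:
        vcov = np.zeros((len(names), len(names)))
    return tm.FitResult(
        coef=pd.Series(beta, index=names),
        vcov=pd.DataFrame(vcov, index=names, columns=names),
        dispersion=1.0, n_obs=0, column_roles={})
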