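import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mhcfdr.beta_core import BetaParams
from mhcfdr.em_fit import FitConfig, fit_mixture
from mhcfdr.synth_eval import SyntheticSpec, generate_synthetic

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


GENERIC_TSV = (
    "peptide\tallele\tic50\tpercent_rank\n"
    "SIINFEKLM\tHLA-A*02:01\t120.5\t0.4\n"
    "GLCTLVAML\tHLA-A*02:01\t3000.0\t2.5\n"
    "NLVPMVATV\tHLA-A*02:01\t45000.0\t55.0\n"
)


@pytest.fixture
def generic_tsv(tmp_path):
    p = tmp_path / "preds.tsv"
    p.write_text(GENERIC_TSV)
    return p


@pytest.fixture(scope="session")
def separated_fit():
    """A labeled synthetic mixture with well-separated components plus its fit.

    True component Beta(2, 6) (mean 0.25), false Beta(7, 2) (mean ~0.78),
    1250:3750 at n=5000 — the standard benchmark-style construction used
    throughout the evaluation tests.
    """
    spec = SyntheticSpec(
        n_true=1250,
        n_false=3750,
        true_params=BetaParams(2.0, 6.0),
        false_params=BetaParams(7.0, 2.0),
        decoy_exclusion_scaled=None,
        seed=42,
    )
    table = generate_synthetic(spec)
    fit = fit_mixture(table, FitConfig())
    return table, fit
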