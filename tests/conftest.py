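import numpy as np
import pytest

from mixrisk.calculate import calc_response
from mixrisk.dose_response import HillParams
from mixrisk.model import RunConfig, assemble_model
from mixrisk.synthetic import gen_synthetic_study


def make_params(tp=100.0, ac50=1.0, slope=1.0, chem="c", assay="a") -> HillParams:
    return HillParams(chemical_id=chem, assay_id=assay, tp=tp,
                      log10_ac50=float(np.log10(ac50)), slope=slope)


@pytest.fixture(scope="session")
def study():
    """Small noisy synthetic study exercising partial assay coverage."""
    return gen_synthetic_study(n_regions=3, n_chems=3, n_assays=2, n_conc=10,
                               noise_sd=5.0, seed=11)


@pytest.fixture(scope="session")
def fitted_model(study):
    cfg = RunConfig(seed=11, n_per_region=50)
    return assemble_model(study.regions, study.exposure, study.concresp,
                          study.css, study.population_inputs, cfg)


@pytest.fixture(scope="session")
def responded_model(study):
    cfg = RunConfig(seed=11, n_per_region=50)
    model = assemble_model(study.regions, study.exposure, study.concresp,
                           study.css, study.population_inputs, cfg)
    model.simulate()
    calc_response(model)
    return model
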