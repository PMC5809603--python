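import pytest

from fertresp import builtin_trials, published_fits, published_marginal_fits


@pytest.fixture(scope="session")
def rice_trials():
    return {t.trial_id: t for t in builtin_trials("rice_table1")}


@pytest.fixture(scope="session")
def wheat_trials():
    return {t.trial_id: t for t in builtin_trials("wheat_table4")}


@pytest.fixture(scope="session")
def datian_n(rice_trials):
    """8-level N trial (Datian county): yields 5051..6600 kg/hm2."""
    return rice_trials["R1"]


@pytest.fixture(scope="session")
def nanan_p(rice_trials):
    return rice_trials["R4"]


@pytest.fixture(scope="session")
def datian_k(rice_trials):
    return rice_trials["R7"]


@pytest.fixture(scope="session")
def pub_rice():
    return published_fits("rice")


@pytest.fixture(scope="session")
def pub_wheat():
    return published_fits("wheat")


@pytest.fixture(scope="session")
def pub_marginal():
    return published_marginal_fits()
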