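import pytest

from vinpbpk import simulate_iv_bolus, studies


@pytest.fixture(scope="session")
def mouse_wt_sim():
    st = studies.mouse_wild_type()
    return simulate_iv_bolus(st.physiology, st.drug, st.dose, t_end=st.t_end)


@pytest.fixture(scope="session")
def mouse_ko_sim():
    st = studies.mouse_knockout()
    return simulate_iv_bolus(st.physiology, st.drug, st.dose, t_end=st.t_end)


@pytest.fixture(scope="session")
def dog_sim():
    st = studies.dog_trial()
    return simulate_iv_bolus(st.physiology, st.drug, st.dose, t_end=st.t_end)
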