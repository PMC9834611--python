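"""Species physiology: resolution of volumes/flows, allometry, config I/O."""

import io

import numpy as np
import pytest

from vinpbpk.physiology import (
    ConfigurationError,
    SpeciesPhysiology,
    allometric_cardiac_output,
    dog,
    dump_physiology,
    get_species,
    human,
    load_physiology,
    mouse,
    resolve_physiology,
)


class TestResolvePhysiology:
    def test_human_liver_volume(self):
        comps = resolve_physiology(human())  # 70 kg, liver 2.57 %BW
        assert comps["liver"].volume == pytest.approx(1.799, abs=1e-3)

    def test_mouse_brain_split(self):
        comps = resolve_physiology(mouse())  # 0.025 kg, brain 1.65 %BW
        v_brain = comps["brain_tissue"].volume + comps["brain_vascular"].volume
        assert v_brain == pytest.approx(4.125e-4, rel=1e-12)
        assert comps["brain_tissue"].volume == pytest.approx(4.00125e-4, rel=1e-12)
        assert comps["brain_vascular"].volume == pytest.approx(1.2375e-5, rel=1e-12)

    def test_flows_are_fraction_of_cardiac_output(self):
        phys = dog()
        comps = resolve_physiology(phys)
        qc = phys.total_cardiac_output()
        assert comps["kidney"].flow == pytest.approx(0.173 * qc)
        assert comps["lung"].flow == pytest.approx(qc)  # central path

    def test_volume_conservation(self):
        for phys in (mouse(), dog(), human()):
            comps = resolve_physiology(phys)
            total = sum(c.volume for c in comps.values())
            assert total <= phys.body_weight / phys.density + 1e-12

    def test_volumes_linear_in_body_weight_flows_allometric(self):
        base = human()
        double = human(body_weight=140.0)
        c1, c2 = resolve_physiology(base), resolve_physiology(double)
        for name in c1:
            assert c2[name].volume == pytest.approx(2.0 * c1[name].volume)
        ratio = c2["kidney"].flow / c1["kidney"].flow
        assert ratio == pytest.approx(2.0**base.co_exponent, rel=1e-12)

    def test_zero_weight_fraction_rejected(self):
        phys = mouse()
        bad = dict(phys.tissue_weight_fraction, kidney=0.0)
        with pytest.raises(ValueError, match="kidney"):
            phys.with_(tissue_weight_fraction=bad)

    def test_missing_tissue_named_in_error(self):
        phys = mouse()
        frac = dict(phys.tissue_weight_fraction)
        del frac["gut"]
        with pytest.raises(ConfigurationError, match="gut"):
            phys.with_(tissue_weight_fraction=frac)

    def test_nonpositive_body_weight_rejected(self):
        with pytest.raises(ValueError):
            mouse(body_weight=-1.0)

    def test_lung_switch(self):
        phys = mouse().with_(lung_weight_fraction=None)
        assert "lung" not in resolve_physiology(phys)


class TestAllometry:
    def test_identity_at_unit_weight(self):
        assert allometric_cardiac_output(1.0, coefficient=7.7) == 7.7

    def test_linear_case(self):
        assert allometric_cardiac_output(0.5, coefficient=10.0, exponent=1.0) == 5.0

    def test_monotone_and_physiologic(self):
        co = [allometric_cardiac_output(bw) for bw in (0.025, 10.0, 70.0)]
        assert co[0] < co[1] < co[2]
        assert 0.5 < co[0] < 2.0  # mouse, L/h
        assert 200.0 < co[2] < 500.0  # human, L/h

    def test_direct_override_wins(self):
        phys = dog().with_(cardiac_output=120.0)
        assert phys.total_cardiac_output() == 120.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            allometric_cardiac_output(0.0)
        with pytest.raises(ValueError):
            allometric_cardiac_output(1.0, coefficient=-1.0)


class TestConfigRoundTrip:
    @pytest.mark.parametrize("factory", [mouse, dog, human])
    def test_yaml_round_trip_preserves_resolution(self, factory):
        phys = factory()
        text = dump_physiology(phys)
        again = load_physiology(io.StringIO(text))
        c1, c2 = resolve_physiology(phys), resolve_physiology(again)
        assert set(c1) == set(c2)
        for name in c1:
            assert c2[name].volume == c1[name].volume
            assert c2[name].flow == c1[name].flow

    def test_unknown_species(self):
        with pytest.raises(ConfigurationError, match="unknown species"):
            get_species("rat")


class TestShippedConfigs:
    @pytest.mark.parametrize("name,factory", [("mouse", mouse), ("dog", dog),
                                              ("human", human)])
    def test_shipped_species_files_match_defaults(self, name, factory):
        from vinpbpk.physiology import shipped_config_path

        loaded = load_physiology(str(shipped_config_path(name)))
        c1 = resolve_physiology(loaded)
        c2 = resolve_physiology(factory())
        for comp in c2:
            assert c1[comp].volume == c2[comp].volume
            assert c1[comp].flow == c2[comp].flow

    def test_shipped_drug_files_match_defaults(self):
        from vinpbpk.pbpk_core import (
            load_drug_parameters,
            vinblastine_dog_human,
            vinblastine_mouse,
        )
        from vinpbpk.physiology import shipped_config_path

        for name, factory in (
            ("vinblastine_mouse", vinblastine_mouse),
            ("vinblastine_dog_human", vinblastine_dog_human),
        ):
            loaded = load_drug_parameters(str(shipped_config_path(name)))
            assert loaded == factory()
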