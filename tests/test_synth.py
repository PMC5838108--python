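import numpy as np
import pytest

import tractprofiles as tp
from tractprofiles.stats import NodeRange
from tractprofiles.synth import (
    Bump,
    LesionSpec,
    MetadataColumn,
    ProfileShape,
    SyntheticSpec,
    _ar1_noise,
)


def _tiny_spec(**kw):
    base = dict(
        n_subjects=4,
        tract_names=["t1", "t2"],
        metric_names=["fa"],
        n_nodes=10,
        seed=3,
    )
    base.update(kw)
    return SyntheticSpec(**base)


class TestGenerate:
    def test_noise_free_limit_reproduces_mean_shape(self):
        shape = ProfileShape(baseline=0.5, bumps=(Bump(5, 2, 0.1),))
        spec = _tiny_spec(
            profiles={"fa": shape},
            subject_sd={"fa": 0.0},
            noise_sd={"fa": 0.0},
        )
        ds = tp.generate(spec)
        mu = shape.mean(10)
        for s in ds.subject_ids:
            np.testing.assert_allclose(ds.profile(s, "t1", "fa"), mu, atol=1e-14)

    def test_seed_determinism(self):
        a = tp.generate(_tiny_spec())
        b = tp.generate(_tiny_spec())
        assert a.equals(b)
        c = tp.generate(_tiny_spec(seed=4))
        assert not a.equals(c)

    def test_metadata_generators(self):
        spec = _tiny_spec(
            n_subjects=200,
            metadata_columns=[
                MetadataColumn("age", "uniform", low=8, high=50),
                MetadataColumn("iq", "normal", mean=100, sd=15),
                MetadataColumn("dx", "categorical", levels=("a", "b"), probs=(0.8, 0.2)),
            ],
        )
        ds = tp.generate(spec)
        assert ds.metadata["age"].between(8, 50).all()
        assert abs(ds.metadata["iq"].mean() - 100) < 5
        assert set(ds.metadata["dx"]) <= {"a", "b"}

    def test_group_effect_shifts_only_window(self):
        from tractprofiles.synth import GroupEffect

        spec = _tiny_spec(
            n_subjects=2,
            subject_sd={"fa": 0.0},
            noise_sd={"fa": 0.0},
            metadata_columns=[MetadataColumn("dx", "categorical", levels=("pat",))],
            group_effects=[GroupEffect("dx", "pat", "fa", "t1", NodeRange(3, 5), 0.2)],
        )
        ds = tp.generate(spec)
        base = tp.generate(_tiny_spec(n_subjects=2, subject_sd={"fa": 0.0},
                                      noise_sd={"fa": 0.0}))
        diff = ds.values[("fa", "t1")] - base.values[("fa", "t1")]
        np.testing.assert_allclose(diff[:, 3:6], 0.2, atol=1e-14)
        np.testing.assert_allclose(np.delete(diff, [3, 4, 5], axis=1), 0, atol=1e-14)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            _tiny_spec(ar1_rho=1.0)
        with pytest.raises(ValueError):
            _tiny_spec(noise_sd={"fa": -0.1})
        with pytest.raises(ValueError):
            _tiny_spec(n_subjects=0)


def test_ar1_lag1_autocorrelation_close_to_rho():
    rng = np.random.default_rng(123)
    rho, sigma = 0.8, 1.0
    eps = _ar1_noise(rng, 1, 10_000, sigma, rho)[0]
    emp = np.corrcoef(eps[:-1], eps[1:])[0, 1]
    assert abs(emp - rho) < 0.05
    assert abs(np.std(eps) - sigma) < 0.05


class TestInjectLesion:
    def _study(self, seed=0):
        spec = SyntheticSpec(
            n_subjects=31,
            tract_names=["cst"],
            metric_names=["md"],
            n_nodes=100,
            seed=seed,
            metadata_columns=[],
        )
        ds = tp.generate(spec)
        return ds, ds.subject_ids[0], ds.subject_ids[1:]

    def test_zero_amplitude_is_identity(self):
        ds, patient, controls = self._study()
        out = tp.inject_lesion(
            ds, LesionSpec(patient, "cst", "md", center=50, amplitude=0.0), controls
        )
        assert out.equals(ds)

    def test_narrow_lesion_only_moves_center_node(self):
        ds, patient, controls = self._study()
        lesion = LesionSpec(patient, "cst", "md", center=50, width=0.1, amplitude=5.0)
        out = tp.inject_lesion(ds, lesion, controls)
        delta = out.profile(patient, "cst", "md") - ds.profile(patient, "cst", "md")
        assert delta[50] > 0
        assert np.all(np.abs(np.delete(delta, 50)) < 1e-10 * max(1, delta[50]))
        zp = tp.subject_zscores(out, patient, "cst", "md", controls)
        # amplitude is in control-SD units, so z at the center is ~5
        base_z = tp.subject_zscores(ds, patient, "cst", "md", controls).z[50]
        assert zp.z[50] == pytest.approx(5.0 + base_z, abs=1e-8)

    def test_negative_sign_lowers_metric(self):
        ds, patient, controls = self._study()
        lesion = LesionSpec(patient, "cst", "md", center=50, amplitude=3.0, sign=-1)
        out = tp.inject_lesion(ds, lesion, controls)
        zp = tp.subject_zscores(out, patient, "cst", "md", controls)
        base = tp.subject_zscores(ds, patient, "cst", "md", controls)
        assert zp.z[50] < base.z[50]

    def test_zero_control_sd_rejected(self):
        from conftest import make_dataset

        ds = make_dataset(
            {("md", "t"): {"p": [0.8, 0.8], "c1": [0.7, 0.71], "c2": [0.7, 0.73]}}
        )
        with pytest.raises(ValueError, match="control SD"):
            tp.inject_lesion(
                ds, LesionSpec("p", "t", "md", center=0), ["c1", "c2"]
            )

    def test_lesion_does_not_touch_other_subjects(self):
        ds, patient, controls = self._study()
        out = tp.inject_lesion(
            ds, LesionSpec(patient, "cst", "md", center=50), controls
        )
        for s in controls:
            np.testing.assert_array_equal(
                out.profile(s, "cst", "md"), ds.profile(s, "cst", "md")
            )


def test_default_spec_is_study_sized():
    spec = tp.default_spec(seed=0)
    ds = tp.generate(spec)
    assert ds.n_subjects == 40
    assert len(ds.tract_names) == 20
    assert ds.metric_names == ["fa", "md", "rd", "ad"]
    assert ds.n_nodes == 100
    assert "age" in ds.metadata.columns
    report = tp.validate(ds)
    assert report.valid
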