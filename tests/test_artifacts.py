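"""k-space corruption operators: locality, realness, severity, determinism."""

import numpy as np
import pytest

from mriwave import (
    ArtifactSpec,
    KSpace,
    Volume,
    apply_artifact,
    apply_herringbone,
    apply_ringing,
    apply_zipper,
    compose_mixture,
    from_kspace,
    sample_artifact_params,
    severity_label,
    to_kspace,
    zscore_normalize,
)
from mriwave.artifacts import (
    SeverityThresholds,
    _mirror,
    _polar_grid,
    compute_severity_thresholds,
    severity_parameter,
    zipper_stripes,
)
from mriwave.metrics import ssim


def ringing_spec(alpha, theta1=30, theta2=70, ri=0.77, re=0.92, axis=0, seed=0):
    return ArtifactSpec(kind="ringing", axis=axis, seed=seed,
                        params={"alpha": alpha, "theta1": theta1, "theta2": theta2,
                                "ri_frac": ri, "re_frac": re})


def herringbone_spec(S=10, sel=0, ks=5, d_frac=0.15, axis=0, seed=0):
    return ArtifactSpec(kind="herringbone", axis=axis, seed=seed,
                        params={"S": S, "selection_point": sel, "ks": ks, "d_frac": d_frac})


def zipper_spec(intensity=30, n=1, var=30 / 256, amp=40 / 256, axis=1, seed=2):
    return ArtifactSpec(kind="zipper", axis=axis, seed=seed,
                        params={"intensity": intensity, "n_artifacts": n,
                                "variability_frac": var, "amplitude_frac": amp})


class TestKSpace:
    def test_round_trip_identity(self, rng):
        x = rng.normal(size=(64, 64))
        assert np.abs(from_kspace(to_kspace(x)) - x).max() < 1e-10

    def test_constant_image_has_single_centered_coefficient(self):
        c = 3.0
        k = to_kspace(np.full((16, 16), c))
        mags = np.abs(k.values)
        assert np.isclose(mags[8, 8], c * 256)
        mags[8, 8] = 0
        assert mags.max() < 1e-9

    def test_parseval(self, rng):
        x = rng.normal(size=(32, 32))
        k = to_kspace(x)
        assert abs(np.sum(x**2) - np.sum(np.abs(k.values) ** 2) / x.size) < 1e-8

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError):
            to_kspace(np.zeros(8))


class TestRinging:
    def test_alpha_one_is_identity(self, phantom):
        out = apply_ringing(phantom, ringing_spec(1.0))
        assert np.abs(out.voxels - phantom.voxels).max() < 1e-9

    def test_empty_sector_is_identity(self, phantom):
        out = apply_ringing(phantom, ringing_spec(0.2, theta1=70, theta2=70))
        assert np.abs(out.voxels - phantom.voxels).max() < 1e-9

    def test_spectral_locality_coefficient_by_coefficient(self, phantom):
        spec = ringing_spec(0.2, theta1=30, theta2=70, ri=0.77, re=0.92)
        out = apply_ringing(phantom, spec)
        nyq = 32
        r, theta = _polar_grid((64, 64))
        ang = (theta - 30.0) % 360.0
        mask = (ang <= 40.0) & (r >= 0.77 * nyq) & (r <= 0.92 * nyq)
        mask = mask | _mirror(mask)
        for idx in (8, 16, 24):
            kin = to_kspace(phantom.voxels[idx]).values
            kout = to_kspace(out.voxels[idx]).values
            assert np.abs(kout[~mask] - kin[~mask]).max() < 1e-6
            assert np.abs(kout[mask] - 0.2 * kin[mask]).max() < 1e-6

    def test_invalid_radii_rejected(self, phantom):
        with pytest.raises(ValueError):
            apply_ringing(phantom, ringing_spec(0.5, ri=0.95, re=0.92))
        with pytest.raises(ValueError, match="Nyquist"):
            apply_ringing(phantom, ringing_spec(0.5, ri=0.9, re=1.2))


class TestHerringbone:
    def test_spectral_locality_of_kernel_and_mirror(self, phantom):
        spec = herringbone_spec(S=10, sel=0, ks=5, d_frac=0.5)
        out = apply_herringbone(phantom, spec)
        n = 64
        c = n // 2
        up = c + 16  # 0.5 * nyquist(32) along +u
        support = np.zeros((n, n), dtype=bool)
        support[up - 2: up + 3, c - 2: c + 3] = True
        mu = 2 * c - up
        support[mu - 2: mu + 3, c - 2: c + 3] = True
        for idx in (10, 20):
            kin = to_kspace(phantom.voxels[idx]).values
            kout = to_kspace(out.voxels[idx]).values
            assert np.abs(kout[~support] - kin[~support]).max() < 1e-6
            assert np.abs(kout[support] - kin[support]).max() > 1e-3  # actually modified

    def test_output_spectrum_is_hermitian(self, phantom):
        out = apply_herringbone(phantom, herringbone_spec(S=18, sel=2, ks=7, d_frac=0.4))
        k = to_kspace(out.voxels[16]).values
        assert np.abs(k - np.conj(_mirror(k))).max() < 1e-6
        assert np.all(np.isreal(out.voxels))

    def test_larger_smoothing_parameter_is_more_severe(self, phantom_bank):
        ssims = {}
        for S in (4, 18):
            vals = []
            for i, v in enumerate(phantom_bank):
                spec = herringbone_spec(S=S, sel=i % 4, ks=5, d_frac=0.3, seed=i)
                out = zscore_normalize(apply_herringbone(v, spec))
                ref = zscore_normalize(v)
                for k in (12, 16, 20):
                    vals.append(ssim(out.voxels[k], ref.voxels[k]))
            ssims[S] = np.mean(vals)
        assert ssims[18] < ssims[4]

    def test_out_of_bounds_kernel_rejected_with_hint(self, phantom):
        with pytest.raises(ValueError, match="grid"):
            apply_herringbone(phantom, herringbone_spec(ks=13, d_frac=0.99))


class TestZipper:
    def test_zero_intensity_is_exact_identity(self, phantom):
        out = apply_zipper(phantom, zipper_spec(intensity=0))
        assert np.array_equal(out.voxels, phantom.voxels)

    def test_stripe_to_background_variance_ratio_is_four(self):
        spec = zipper_spec(intensity=30)
        stripes = zipper_stripes(spec, 256)
        (a, b), = stripes
        assert b - a >= 20
        vol = Volume(np.zeros((1, 256, 256)), subject_id="flat")
        out = apply_zipper(vol, spec)
        sl = out.voxels[0]
        inside = sl[a:b].var()
        outside = np.concatenate([sl[:a], sl[b:]]).var()
        assert abs(inside / outside - 4.0) < 0.4  # analytic ratio 4.0 within 10%
        assert abs(inside - 30**2 / 3) / (30**2 / 3) < 0.1

    def test_stripes_respect_axis(self, phantom):
        spec = zipper_spec(axis=2)
        out = apply_zipper(phantom, spec)
        diff = np.abs(out.voxels - phantom.voxels)
        # amplitude profile varies only along the propagation axis
        prof = diff.max(axis=(0, 1))
        assert prof.max() > 2 * np.median(prof) * 0.9  # stripes visible

    def test_determinism(self, phantom):
        a = apply_zipper(phantom, zipper_spec())
        b = apply_zipper(phantom, zipper_spec())
        assert np.array_equal(a.voxels, b.voxels)


class TestSampling:
    @pytest.mark.parametrize("kind", ["ringing", "herringbone", "zipper"])
    def test_ten_thousand_draws_stay_in_table_ranges(self, kind):
        for seed in range(10_000):
            spec = sample_artifact_params(kind, seed)
            spec.validate()
            p = spec.params
            if kind == "ringing":
                assert p["theta2"] - 100 <= p["theta1"] <= p["theta2"] - 10
                assert 0.0 <= p["alpha"] <= 1.0
            elif kind == "herringbone":
                assert 3 <= p["S"] <= 20
                assert p["ks"] % 2 == 1 and 3 <= p["ks"] <= 13
            else:
                assert 15 <= p["intensity"] <= 50
                assert 1 <= p["n_artifacts"] <= 16

    def test_fixed_seed_gives_identical_spec(self):
        assert sample_artifact_params("ringing", 5) == sample_artifact_params("ringing", 5)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            sample_artifact_params("motion", 0)


class TestMixture:
    def test_single_element_equals_single_operator(self, phantom):
        spec = zipper_spec()
        assert np.array_equal(compose_mixture(phantom, [spec]).voxels,
                              apply_zipper(phantom, spec).voxels)

    def test_application_order_matters(self, phantom):
        s1 = ringing_spec(0.2)
        s2 = zipper_spec()
        a = compose_mixture(phantom, [s1, s2])
        b = compose_mixture(phantom, [s2, s1])
        assert np.abs(a.voxels - b.voxels).max() > 0

    def test_three_way_mixture_records_specs_in_order(self, phantom):
        specs = [ringing_spec(0.3), zipper_spec(), herringbone_spec()]
        out = compose_mixture(phantom, specs)
        assert out.provenance == "corrupted"
        assert [s.kind for s in out.applied_specs] == ["ringing", "zipper", "herringbone"]

    def test_empty_list_rejected(self, phantom):
        with pytest.raises(ValueError):
            compose_mixture(phantom, [])


class TestSeverity:
    def test_herringbone_reference_thresholds(self):
        th = SeverityThresholds("herringbone", 6.0, 16.0)
        assert severity_label(herringbone_spec(S=5), th) == "mild"
        assert severity_label(herringbone_spec(S=6), th) == "mild"  # boundary p25
        assert severity_label(herringbone_spec(S=10), th) == "moderate"
        assert severity_label(herringbone_spec(S=16), th) == "severe"

    def test_kind_mismatch_rejected(self):
        th = SeverityThresholds("zipper", 22.0, 41.0)
        with pytest.raises(ValueError):
            severity_label(herringbone_spec(), th)

    def test_empirical_quantiles_give_quarter_tails(self):
        specs = [sample_artifact_params("zipper", s) for s in range(400)]
        th = compute_severity_thresholds(specs)["zipper"]
        labels = [severity_label(s, th) for s in specs]
        frac_mild = labels.count("mild") / len(labels)
        frac_severe = labels.count("severe") / len(labels)
        assert 0.15 <= frac_mild <= 0.35
        assert 0.15 <= frac_severe <= 0.35

    def test_ringing_severity_grows_with_attenuation_depth(self):
        assert severity_parameter(ringing_spec(0.9)) < severity_parameter(ringing_spec(0.1))


class TestRealnessAndDeterminism:
    @pytest.mark.parametrize("kind", ["ringing", "herringbone", "zipper"])
    def test_outputs_real_finite_and_deterministic(self, phantom, kind):
        spec = sample_artifact_params(kind, 99)
        a = apply_artifact(phantom, spec)
        b = apply_artifact(phantom, spec)
        assert np.isrealobj(a.voxels)
        assert np.all(np.isfinite(a.voxels))
        assert np.array_equal(a.voxels, b.voxels)
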