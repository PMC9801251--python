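"""Synthetic generators: phantom geometry against brute-force oracles,
cohort moments against Monte-Carlo, trial statistics against closed
forms."""

import numpy as np
import pytest
from dataclasses import replace

from vtamap.choice import TaskDesign, accept_probability
from vtamap.errors import GeometryError, ParameterError
from vtamap.synthetic import (
    BilateralNuclei,
    CohortSpec,
    PhantomSpec,
    cohort_table,
    make_cohort,
    make_phantom,
    make_trials,
)


def brute_force_ellipsoid_count(center, semi, shape):
    """Independent lattice-point enumeration for the ellipsoid oracle."""
    cx, cy, cz = center
    a, b, c = semi
    count = 0
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 <= 1.0:
                    count += 1
    return count


def test_vta_voxel_count_matches_brute_force_enumeration():
    spec = PhantomSpec(noise_sd=0.0, seed=0)
    _, _, truth = make_phantom(spec)
    g = spec.vta_geometry
    mid = spec.midline_x
    one_side = brute_force_ellipsoid_count(
        (mid - g.lateral_offset_vox, *g.center_yz_vox), g.semi_axes_vox, spec.grid_shape
    )
    assert truth.masks["vta"].n_voxels == 2 * one_side
    assert truth.true_vta_volume_mm3 == pytest.approx(2 * one_side * 0.4**3)


def test_noiseless_tier_map_and_mask_structure(noiseless_phantom):
    spec, mt, non_mt, truth = noiseless_phantom
    brain = truth.masks["brain"].values
    ratio = mt.values[brain] / non_mt.values[brain]
    assert np.allclose(ratio, truth.true_tier_map.values[brain], atol=1e-12)
    # nested/disjoint mask contract
    vta, sn = truth.masks["vta"].values, truth.masks["sn"].values
    mb = truth.masks["midbrain"].values
    assert not np.any(vta & sn)
    assert np.all(mb[vta]) and np.all(mb[sn])
    assert np.all(brain[mb])
    # SN tier above VTA tier over the planted masks
    tiers = truth.true_tier_map.values
    assert tiers[sn].mean() > tiers[vta].mean()


def test_mirror_symmetry_of_nuclei(noiseless_phantom):
    spec, _, _, truth = noiseless_phantom
    for roi in ("vta", "sn"):
        m = truth.masks[roi].values
        assert np.array_equal(m, m[::-1, :, :])
        nx = m.shape[0]
        left = m[: nx // 2].sum()
        right = m[nx // 2 :].sum()
        assert left == right


def test_phantom_determinism_and_noise_sd():
    spec = PhantomSpec(noise_sd=0.01, seed=9)
    mt1, non1, _ = make_phantom(spec)
    mt2, non2, _ = make_phantom(spec)
    assert np.array_equal(mt1.values, mt2.values)
    assert np.array_equal(non1.values, non2.values)
    # enhancement-domain noise sd equals noise_sd
    _, _, truth = make_phantom(spec)
    brain = truth.masks["brain"].values
    resid = mt1.values[brain] / non1.values[brain] - truth.true_tier_map.values[brain]
    assert resid.std() == pytest.approx(0.01, rel=0.05)


def test_phantom_geometry_validation():
    with pytest.raises(ParameterError):
        make_phantom(PhantomSpec(tier_means={"csf": 0.85, "wm": 0.95, "vta": 1.12, "sn": 1.08}))
    with pytest.raises(GeometryError):
        # nucleus pushed outside the midbrain
        make_phantom(PhantomSpec(vta_geometry=BilateralNuclei(25.0, (31.5, 23.5), (3.0, 4.0, 3.0))))
    with pytest.raises(GeometryError):
        # overlapping nuclei
        make_phantom(PhantomSpec(sn_geometry=BilateralNuclei(4.5, (27.5, 23.5), (3.5, 5.0, 3.0))))


def test_cohort_null_moments_over_seeds():
    """Null generator: group differences and the intensity-bias
    correlation average to ~0 over many seeds."""
    diffs, corrs = [], []
    for s in range(300):
        subs = make_cohort(CohortSpec.null(seed=s, n_hc=8, n_ma=8))
        t = cohort_table(subs)
        hc = t[t["group"] == "HC"]["vta_intensity_norm"]
        ma = t[t["group"] == "MA"]["vta_intensity_norm"]
        diffs.append(ma.mean() - hc.mean())
        corrs.append(np.corrcoef(t["vta_intensity_norm"], t["bias_external"])[0, 1])
    se_diff = CohortSpec().intensity_sd * np.sqrt(2 / 8) / np.sqrt(300)
    assert abs(np.mean(diffs)) < 4 * se_diff
    assert abs(np.mean(corrs)) < 4 / np.sqrt(16 * 300)


def test_cohort_planted_effect_size_recovered():
    """Pooled-SD standardized intensity difference approaches the
    planted d = -0.8 over many seeds (Monte-Carlo oracle)."""
    ds = []
    for s in range(800):
        spec = replace(CohortSpec.null(seed=s), effect_intensity_d=-0.8)
        t2 = cohort_table(make_cohort(spec))
        hc = t2[t2["group"] == "HC"]["vta_intensity_norm"].to_numpy()
        ma = t2[t2["group"] == "MA"]["vta_intensity_norm"].to_numpy()
        sp = np.sqrt(((hc.size - 1) * hc.var(ddof=1) + (ma.size - 1) * ma.var(ddof=1)) / (hc.size + ma.size - 2))
        ds.append((ma.mean() - hc.mean()) / sp)
    # the sample standardized difference overestimates |d| by the usual
    # small-sample factor 1 + 3/(4*df - 1); df = 41 here
    expected = -0.8 * (1 + 3 / (4 * 41 - 1))
    assert np.mean(ds) == pytest.approx(expected, abs=0.05)


def test_cohort_planted_correlation_at_scale():
    subs = make_cohort(CohortSpec(seed=123, n_hc=5000, n_ma=5000, r_intensity_bias=0.4,
                                  effect_intensity_d=0.0, effect_volume_d=0.0, effect_sigma_d=0.0))
    t = cohort_table(subs)
    r = np.corrcoef(t["vta_intensity_norm"], t["bias_external"])[0, 1]
    assert r == pytest.approx(0.4, abs=0.02)


def test_cohort_determinism_and_sizes():
    a = make_cohort(CohortSpec(seed=5))
    b = make_cohort(CohortSpec(seed=5))
    assert [s.true_vta_intensity for s in a] == [s.true_vta_intensity for s in b]
    assert sum(s.group == "HC" for s in a) == 22
    assert sum(s.group == "MA" for s in a) == 21
    assert all(s.true_sigma_external > 0 and s.true_sigma_internal > 0 for s in a)
    with pytest.raises(ParameterError):
        CohortSpec(r_intensity_bias=1.0).validate()


def test_trials_acceptance_rate_matches_closed_form():
    """Monte-Carlo acceptance frequency at 50k trials matches the
    analytic mean of the sigmoid over the design grid."""
    from vtamap.synthetic import SubjectTruth

    subj = SubjectTruth(
        subject_id="s", group="HC", sex="F",
        true_bias_internal=0.0, true_bias_external=0.15,
        true_sigma_internal=0.3, true_sigma_external=0.25,
        true_vta_intensity=1.08, true_vta_volume=19.0,
        true_sn_intensity=1.12, true_brain_volume_mm3=1.2e6,
    )
    design = TaskDesign(trials_per_cell=800, conditions=("external",))  # 51200 trials
    trials = make_trials(subj, design, seed=77)
    e, r = design.grid()
    analytic = float(np.mean(accept_probability(e, r, 0.15, 0.25)))
    mc = trials["response"].mean()
    assert mc == pytest.approx(analytic, abs=3 * np.sqrt(0.25 / len(trials)) + 0.005)


def test_work_required_fraction():
    from vtamap.synthetic import SubjectTruth

    subj = SubjectTruth(
        subject_id="s", group="HC", sex="F",
        true_bias_internal=0.0, true_bias_external=0.0,
        true_sigma_internal=0.3, true_sigma_external=0.3,
        true_vta_intensity=1.08, true_vta_volume=19.0,
        true_sn_intensity=1.12, true_brain_volume_mm3=1.2e6,
    )
    trials = make_trials(subj, TaskDesign(trials_per_cell=40), seed=3)
    assert trials["work_required"].mean() == pytest.approx(0.3, abs=0.02)
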