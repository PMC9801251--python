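"""Reusable validation studies.

Each function runs one property-level study of the pipeline on
synthetic data — phantom segmentation recovery, SN>VTA intensity
ordering, EM benchmark behavior, choice-model parameter recovery,
type-I/power calibration of the statistical battery, and the
effect-direction detection study — and returns plain numbers. The
test suite asserts on these numbers; the acceptance script reports
them.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import stats as sps

from .choice import TaskDesign, fit_discounting
from .enhancement import compute_enhancement
from .gmm import fit_gmm_em
from .metrics import dice, roi_mean_intensity
from .segmentation import AnatomicalConstraints, segment_vta_sn
from .stats import run_paper_battery, ttest_two_sample
from .synthetic import CohortSpec, PhantomSpec, SubjectTruth, cohort_table, make_cohort, make_phantom, make_trials

__all__ = [
    "segment_phantom",
    "phantom_recovery_study",
    "ordering_study",
    "em_benchmark",
    "choice_recovery_study",
    "calibration_study",
    "power_study",
    "analytic_welch_power",
    "effect_detection_study",
]


def segment_phantom(spec: PhantomSpec, seg_seed: int = 0):
    """Generate a phantom, run enhancement + segmentation, and return
    (truth, enh, segmentation result)."""
    mt, non_mt, truth = make_phantom(spec)
    enh, valid = compute_enhancement(mt, non_mt, truth.masks["brain"])
    constraints = AnatomicalConstraints(midbrain=truth.masks["midbrain"], midline_x=spec.midline_x)
    seg = segment_vta_sn(enh, valid, constraints, seed=seg_seed)
    return truth, enh, seg


def phantom_recovery_study(noise_sd: float, seeds) -> dict:
    """VTA recovery against planted truth over phantom seeds.

    Returns per-seed Dice, the mean absolute error of the recovered
    mean VTA enhancement vs the planted tier, and the SN/VTA means.
    """
    dices, tier_errors, sn_means, vta_means = [], [], [], []
    for seed in seeds:
        spec = PhantomSpec(noise_sd=noise_sd, seed=int(seed))
        truth, enh, seg = segment_phantom(spec, seg_seed=int(seed))
        dices.append(dice(seg.vta, truth.masks["vta"]))
        vta_mean = roi_mean_intensity(seg.vta, enh)
        sn_mean = roi_mean_intensity(seg.sn, enh)
        tier_errors.append(abs(vta_mean - spec.tier_means["vta"]))
        vta_means.append(vta_mean)
        sn_means.append(sn_mean)
    return {
        "dice": np.asarray(dices),
        "tier_abs_error": np.asarray(tier_errors),
        "vta_mean": np.asarray(vta_means),
        "sn_mean": np.asarray(sn_means),
    }


def ordering_study(n_seeds: int, noise_sd: float = 0.01, seed0: int = 0) -> dict:
    """Fraction of phantom seeds on which recovered mean(SN) > mean(VTA)."""
    res = phantom_recovery_study(noise_sd, range(seed0, seed0 + n_seeds))
    ok = res["sn_mean"] > res["vta_mean"]
    return {"fraction_sn_gt_vta": float(ok.mean()), "n_seeds": n_seeds, **res}


def em_benchmark(seed: int = 0, n_per_comp: int = 500, mu=(0.0, 5.0)) -> dict:
    """Two-component 1-D benchmark: recovery vs the known assignment and
    log-likelihood agreement with scikit-learn's mixture fitter started
    from the same initialization."""
    rng = np.random.default_rng(seed)
    x0 = rng.normal(mu[0], 1.0, n_per_comp)
    x1 = rng.normal(mu[1], 1.0, n_per_comp)
    x = np.concatenate([x0, x1])
    sample_means = np.array([x0.mean(), x1.mean()])
    init_means = np.quantile(x, [0.0, 1.0])

    model = fit_gmm_em(x, k=2, seed=seed, init_means=init_means, tol=1e-12, max_iter=2000)
    mean_err = float(np.max(np.abs(np.sort(model.means) - np.sort(sample_means))))

    from sklearn.mixture import GaussianMixture  # independent reference

    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        weights_init=np.array([0.5, 0.5]),
        means_init=init_means.reshape(-1, 1),
        precisions_init=(1.0 / x.var()) * np.ones((2, 1, 1)),
        tol=1e-12,
        reg_covar=1e-300,
        max_iter=2000,
        n_init=1,
    )
    gm.fit(x.reshape(-1, 1))
    ref_loglik = float(gm.score(x.reshape(-1, 1)) * x.size)

    monotone = bool(np.all(np.diff(model.loglik_trace) >= -1e-8))

    xk = rng.normal(2.0, 3.0, 400)
    m1 = fit_gmm_em(xk, k=1)
    k1_err = float(max(abs(m1.means[0] - xk.mean()), abs(m1.variances[0] - xk.var())))

    return {
        "mean_recovery_max_abs_error": mean_err,
        "loglik": model.loglik,
        "ref_loglik": ref_loglik,
        "loglik_gap": abs(model.loglik - ref_loglik),
        "monotone": monotone,
        "k1_closed_form_max_abs_error": k1_err,
        "n": int(x.size),
    }


def choice_recovery_study(
    n_subjects: int = 100,
    trial_counts=(64, 256, 1024),
    true_bias: float = 0.1,
    true_sigma: float = 0.3,
    seed: int = 0,
    n_starts: int = 8,
) -> dict:
    """Parameter recovery for the external-condition discounting fit.

    Simulates ``n_subjects`` subjects at the fixed true (bias, sigma)
    for each trial count (factorial 8x8 design repeated), fits by MAP,
    and returns the median absolute bias error and median relative
    sigma error per trial count.
    """
    ss = np.random.SeedSequence(seed)
    child = [int(s % 2**31) for s in ss.generate_state(2 * n_subjects * len(trial_counts), dtype=np.uint64)]
    out = {"trial_counts": list(trial_counts), "median_abs_bias_error": [], "median_rel_sigma_error": []}
    idx = 0
    for n_trials in trial_counts:
        reps = max(1, int(round(n_trials / 64)))
        design = TaskDesign(trials_per_cell=reps, conditions=("external",))
        bias_err, sigma_err = [], []
        for i in range(n_subjects):
            subj = SubjectTruth(
                subject_id=f"rec-{i}",
                group="HC",
                sex="F",
                true_bias_internal=0.0,
                true_bias_external=true_bias,
                true_sigma_internal=true_sigma,
                true_sigma_external=true_sigma,
                true_vta_intensity=1.08,
                true_vta_volume=19.0,
                true_sn_intensity=1.12,
                true_brain_volume_mm3=1.2e6,
            )
            trials = make_trials(subj, design, seed=child[idx]); idx += 1
            fit = fit_discounting(trials, "external", seed=child[idx], n_starts=n_starts); idx += 1
            bias_err.append(abs(fit.bias - true_bias))
            sigma_err.append(abs(fit.sigma - true_sigma) / true_sigma)
        out["median_abs_bias_error"].append(float(np.median(bias_err)))
        out["median_rel_sigma_error"].append(float(np.median(sigma_err)))
    return out


def calibration_study(n_seeds: int = 1000, alpha: float = 0.05, seed0: int = 0) -> dict:
    """Type-I error of every battery test under the null cohort generator."""
    reject_counts: dict[str, int] = {}
    for s in range(seed0, seed0 + n_seeds):
        table = cohort_table(make_cohort(CohortSpec.null(seed=s)))
        report = run_paper_battery(table, alpha=alpha)
        for name, sig in report.significant.items():
            reject_counts[name] = reject_counts.get(name, 0) + int(sig)
    rates = {k: v / n_seeds for k, v in reject_counts.items()}
    return {
        "rates": rates,
        "min_rate": float(min(rates.values())),
        "max_rate": float(max(rates.values())),
        "n_seeds": n_seeds,
        "alpha": alpha,
    }


def power_study(d: float = 1.0, n_seeds: int = 1000, alpha: float = 0.05, seed0: int = 0) -> dict:
    """Empirical power of the group intensity test at planted effect d."""
    hits = 0
    for s in range(seed0, seed0 + n_seeds):
        spec = CohortSpec.null(seed=s)
        spec = replace(spec, effect_intensity_d=d)
        table = cohort_table(make_cohort(spec))
        hc = table[table["group"] == "HC"]["vta_intensity_norm"]
        ma = table[table["group"] == "MA"]["vta_intensity_norm"]
        res = ttest_two_sample(ma, hc, variant="welch")
        hits += int(res.p_two_sided <= alpha)
    return {"power": hits / n_seeds, "n_seeds": n_seeds, "d": d}


def analytic_welch_power(d: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """Noncentral-t power of the two-sided two-sample test (the oracle
    for the simulated power)."""
    df = n1 + n2 - 2
    nc = abs(d) * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


def effect_detection_study(n_seeds: int = 20, alpha: float = 0.05, seed0: int = 0) -> dict:
    """Run the battery on cohorts with the planted default effect
    directions; count how often the VTA group difference, the SN
    control difference, and the intensity-external-bias association are
    flagged."""
    vta_flags = sn_flags = bias_flags = 0
    for s in range(seed0, seed0 + n_seeds):
        table = cohort_table(make_cohort(CohortSpec(seed=s)))
        report = run_paper_battery(table, alpha=alpha)
        vta_flags += int(report.significant["group_vta_intensity_norm"])
        sn_flags += int(report.significant["group_sn_intensity"])
        bias_flags += int(report.significant["intensity_on_bias_external_z"])
    return {
        "n_seeds": n_seeds,
        "vta_flag_fraction": vta_flags / n_seeds,
        "sn_flag_fraction": sn_flags / n_seeds,
        "bias_assoc_flag_fraction": bias_flags / n_seeds,
    }
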