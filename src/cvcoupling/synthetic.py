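"""Seeded generator of coupled BBI/SBP/DBP beat series.

The generator is a linear stochastic difference-equation model of the
closed-loop interaction between heart period and arterial pressure:

    SBP_n = mu_s + ar_s (SBP_{n-1} - mu_s) + g_mech (BBI_{n-d} - mu_b)
            + A_r sin(2 pi f_r t_n) + e_s
    BBI_n = mu_b + ar_b (BBI_{n-1} - mu_b) + g_baro (SBP_{n-d} - mu_s) + e_b
    DBP_n = mu_d + dia_link (SBP_n - mu_s) + e_d

``g_baro`` (ms/mmHg) is the baroreflex arm (pressure drives heart period),
``g_mech`` (mmHg/ms) the mechanical/runoff arm (heart period drives pressure),
``dia_link`` ties the diastogram to the systogram, and the sinusoid injects
respiratory modulation so a high-frequency band exists.  Ectopic beats are
injected by halving a beat interval at rate ``ectopic_rate``.

The cross-couplings act with a delay of ``coupling_delay = d`` beats
(default 2).  The baroreflex and mechanical feedback latencies are on the
order of one to a few seconds; a delay of two beats also keeps the directed
interactions identifiable after the series are linearly interpolated onto
the 2 Hz grid, whose interpolation looks one beat ahead and therefore folds
any single-beat-lag influence into an instantaneous correlation that
directed-coherence estimators deliberately ignore.

Three default group profiles (healthy controls CON, low-risk and high-risk
dilated-cardiomyopathy patients LR/HR) encode the qualitative cohort
structure the estimators are meant to resolve: heart-rate variability falls
and short-term pressure variability rises CON -> LR -> HR, the baroreflex
gain weakens with risk, and the cardiac -> pressure influence strengthens
with risk.  Between-subject heterogeneity is drawn per subject around the
profile values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .exceptions import ParameterError, StabilityError, ValidationError
from .io_preprocess import BeatSeries


@dataclass(frozen=True)
class GroupProfile:
    """Parameters of one synthetic group.

    Units: ``mu_bbi``/``sd_bbi`` ms; ``mu_sbp``/``sd_sbp``/``mu_dbp`` mmHg;
    ``gain_baroreflex`` ms/mmHg; ``gain_mechanical`` mmHg/ms; ``resp_freq``
    Hz; ``resp_amp`` mmHg.  ``sd_bbi``/``sd_sbp`` are target *marginal*
    standard deviations: innovation variances are solved from the stationary
    covariance equations of the coupled recursion so the simulated marginals
    match the targets (up to the respiratory term and ectopic injections).
    ``between_mean_frac`` / ``between_scale_frac`` are relative per-subject
    standard deviations applied to the means and to the sds/gains.
    """

    name: str
    mu_bbi: float
    sd_bbi: float
    mu_sbp: float
    sd_sbp: float
    mu_dbp: float
    ar_bbi: float
    ar_sbp: float
    gain_baroreflex: float
    gain_mechanical: float
    dia_link: float = 0.5
    coupling_delay: int = 2
    sd_dbp_noise: float = 1.0
    resp_freq: float = 0.25
    resp_amp: float = 2.0
    ectopic_rate: float = 0.005
    between_mean_frac: float = 0.0
    between_scale_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.sd_bbi <= 0 or self.sd_sbp <= 0:
            raise ValidationError("sd_bbi and sd_sbp must be positive")
        if not (abs(self.ar_bbi) < 1 and abs(self.ar_sbp) < 1):
            raise ValidationError("AR coefficients must lie in (-1, 1)")
        if not (0 <= self.ectopic_rate < 0.5):
            raise ValidationError("ectopic_rate must lie in [0, 0.5)")
        if self.coupling_delay < 1:
            raise ValidationError("coupling_delay must be at least 1 beat")


@dataclass
class SyntheticCohort:
    subjects: list[BeatSeries]
    seed: int
    profiles: list[GroupProfile]


def _spectral_radius(profile: GroupProfile) -> float:
    m = np.array([
        [profile.ar_bbi, profile.gain_baroreflex],
        [profile.gain_mechanical, profile.ar_sbp],
    ])
    return float(np.max(np.abs(np.linalg.eigvals(m))))


def _innovation_variances(p: GroupProfile) -> tuple[float, float]:
    """Innovation variances (q_bbi, q_sbp) reproducing the target marginals.

    With state z_n = A z_{n-1} + e_n the stationary covariance S solves
    S = A S A' + Q; fixing diag(S) to the profile's (sd_bbi^2, sd_sbp^2)
    and solving for the cross-covariance yields Q in closed form.  Targets
    that the couplings alone already exceed are clipped to a 5% variance
    floor (the marginal then comes out slightly above target).
    """
    a_b, a_s = p.ar_bbi, p.ar_sbp
    g_b, g_m = p.gain_baroreflex, p.gain_mechanical
    v_b, v_s = p.sd_bbi**2, p.sd_sbp**2
    denom = 1.0 - a_b * a_s - g_b * g_m
    if denom <= 1e-6:
        raise StabilityError("coupled recursion has no stationary solution")
    c = (a_b * g_m * v_b + g_b * a_s * v_s) / denom
    q_b = v_b - (a_b**2 * v_b + g_b**2 * v_s + 2 * a_b * g_b * c)
    q_s = v_s - (g_m**2 * v_b + a_s**2 * v_s + 2 * g_m * a_s * c)
    return max(q_b, 0.05 * v_b), max(q_s, 0.05 * v_s)


def _jitter(profile: GroupProfile, rng: np.random.Generator) -> GroupProfile:
    """Draw a subject-level parameter set around the group profile."""
    fm, fs = profile.between_mean_frac, profile.between_scale_frac
    if fm == 0 and fs == 0:
        return profile
    mul_m = lambda v: v * (1.0 + fm * rng.standard_normal())
    mul_s = lambda v: v * float(np.exp(fs * rng.standard_normal()))
    for _ in range(20):
        cand = replace(
            profile,
            mu_bbi=mul_m(profile.mu_bbi),
            mu_sbp=mul_m(profile.mu_sbp),
            mu_dbp=mul_m(profile.mu_dbp),
            sd_bbi=mul_s(profile.sd_bbi),
            sd_sbp=mul_s(profile.sd_sbp),
            gain_baroreflex=mul_s(profile.gain_baroreflex),
            gain_mechanical=mul_s(profile.gain_mechanical),
            between_mean_frac=0.0,
            between_scale_frac=0.0,
        )
        if cand.mu_dbp < cand.mu_sbp and _spectral_radius(cand) < 1.0:
            return cand
    return replace(profile, between_mean_frac=0.0, between_scale_frac=0.0)


def generate_subject(
    profile: GroupProfile,
    n_beats: int = 1800,
    seed: int = 0,
    subject_id: str | None = None,
) -> BeatSeries:
    """Simulate one subject from the coupled difference-equation model."""
    if n_beats < 100:
        raise ParameterError("n_beats must be at least 100")
    rho = _spectral_radius(profile)
    if rho >= 1.0:
        raise StabilityError(f"coupled recursion unstable (spectral radius {rho:.3f} >= 1)")
    rng = np.random.default_rng(seed)
    p = _jitter(profile, rng)

    q_b, q_s = _innovation_variances(p)
    sig_b, sig_s = np.sqrt(q_b), np.sqrt(q_s)

    burn = 200
    n_total = n_beats + burn
    bbi = np.empty(n_total)
    sbp = np.empty(n_total)
    dbp = np.empty(n_total)
    bbi[0], sbp[0] = p.mu_bbi, p.mu_sbp
    e_b = sig_b * rng.standard_normal(n_total)
    e_s = sig_s * rng.standard_normal(n_total)
    e_d = p.sd_dbp_noise * rng.standard_normal(n_total)
    t = 0.0
    lag = p.coupling_delay
    for n in range(1, n_total):
        t += bbi[n - 1] / 1000.0
        resp = p.resp_amp * np.sin(2 * np.pi * p.resp_freq * t)
        nl = max(n - lag, 0)
        sbp[n] = (p.mu_sbp + p.ar_sbp * (sbp[n - 1] - p.mu_sbp)
                  + p.gain_mechanical * (bbi[nl] - p.mu_bbi) + resp + e_s[n])
        bbi[n] = (p.mu_bbi + p.ar_bbi * (bbi[n - 1] - p.mu_bbi)
                  + p.gain_baroreflex * (sbp[nl] - p.mu_sbp) + e_b[n])
    dbp[:] = p.mu_dbp + p.dia_link * (sbp - p.mu_sbp) + e_d

    bbi, sbp, dbp = bbi[burn:], sbp[burn:], dbp[burn:]
    bbi = np.maximum(bbi, 250.0)  # physiological floor

    if p.ectopic_rate > 0:
        n_ect = int(round(p.ectopic_rate * n_beats))
        if n_ect:
            pos = rng.choice(np.arange(5, n_beats - 5), size=n_ect, replace=False)
            bbi[pos] *= 0.5

    bad = dbp >= sbp
    if bad.any():
        warnings.warn(f"clipped {int(bad.sum())} beats where dbp >= sbp", stacklevel=2)
        dbp[bad] = sbp[bad] - 1.0

    return BeatSeries(
        subject_id=subject_id or f"{p.name}_{seed}",
        group=p.name if p.name in ("CON", "IDC_LR", "IDC_HR") else "UNKNOWN",
        bbi=bbi, sbp=sbp, dbp=dbp,
    )


def generate_cohort(
    profiles: Sequence[GroupProfile],
    n_per_group: int = 20,
    n_beats: int = 1800,
    seed: int = 0,
) -> SyntheticCohort:
    """Generate a labelled cohort; per-subject seeds derive from the master seed."""
    if not profiles:
        raise ParameterError("at least one profile required")
    if n_per_group < 1:
        raise ParameterError("n_per_group must be at least 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(profiles) * n_per_group)]
    subjects = []
    k = 0
    for profile in profiles:
        for i in range(n_per_group):
            subjects.append(generate_subject(
                profile, n_beats=n_beats, seed=child_seeds[k],
                subject_id=f"{profile.name}_{i:03d}",
            ))
            k += 1
    return SyntheticCohort(subjects=subjects, seed=seed, profiles=list(profiles))


def default_profiles() -> dict[str, GroupProfile]:
    """Shipped default group profiles (CON / IDC_LR / IDC_HR).

    Means and marginal standard deviations follow the magnitudes typical of
    30-min resting recordings in healthy controls vs. dilated-cardiomyopathy
    patients (BBI mean ~884/907/828 ms, BBI sd ~48/37/33 ms CON/LR/HR).
    Coupling gains are model defaults chosen so the baroreflex arm weakens
    and the cardiac -> pressure arm strengthens with risk, making the
    control group pressure-driven-to-bidirectional and the high-risk group
    cardiac-driven in directed-coupling analysis.
    """
    return {
        "CON": GroupProfile(
            name="CON", mu_bbi=883.79, sd_bbi=47.82, mu_sbp=122.5, sd_sbp=3.5,
            mu_dbp=60.6, ar_bbi=0.45, ar_sbp=0.5,
            gain_baroreflex=8.0, gain_mechanical=0.012,
            dia_link=0.5, resp_amp=1.0, ectopic_rate=0.004,
            between_mean_frac=0.05, between_scale_frac=0.15,
        ),
        "IDC_LR": GroupProfile(
            name="IDC_LR", mu_bbi=906.95, sd_bbi=36.98, mu_sbp=112.6, sd_sbp=4.0,
            mu_dbp=58.5, ar_bbi=0.45, ar_sbp=0.45,
            gain_baroreflex=5.0, gain_mechanical=0.035,
            dia_link=0.55, resp_amp=1.3, ectopic_rate=0.006,
            between_mean_frac=0.05, between_scale_frac=0.15,
        ),
        "IDC_HR": GroupProfile(
            name="IDC_HR", mu_bbi=828.42, sd_bbi=33.44, mu_sbp=121.3, sd_sbp=5.5,
            mu_dbp=61.5, ar_bbi=0.8, ar_sbp=0.4,
            gain_baroreflex=0.5, gain_mechanical=0.12,
            dia_link=0.6, resp_amp=3.5, ectopic_rate=0.008,
            between_mean_frac=0.05, between_scale_frac=0.15,
        ),
    }
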