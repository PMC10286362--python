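"""Synthetic-data generators with embedded ground truth.

Every input the analysis modules consume can be generated here with a
known, recoverable ground truth: multi-echo T2 decays, stereotyped
evoked-potential sweeps, coupled LFP pairs, cohort tables with planted
group effects and planted age-confounded FA-cognition associations, and
activation-pattern sets for the memory network.  Generators are
deterministic under a fixed seed and return ``(data, truth)`` so
recovery tests can close the loop.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .memnet import ModelConfig, Pattern, sample_overlap_pair, sample_pattern
from .signal_quant import DEFAULT_TE, MsmeSeries, SweepTrace, biexp_model

__all__ = [
    "synth_msme",
    "synth_evoked",
    "synth_paired_pulse",
    "synth_ltp_pair",
    "synth_lfp_pair",
    "synth_cohort",
    "synth_patterns",
    "DEFAULT_ROI_DELTAS",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Multi-echo relaxometry
# ---------------------------------------------------------------------------

def synth_msme(myelin_fraction: float = 0.15, t2_fast: float = 15.0,
               t2_slow: float = 80.0, s0: float = 1000.0,
               te: np.ndarray | None = None, noise_sigma: float = 0.0,
               noise: str = "gaussian", n_reps: int = 2,
               seed: np.random.Generator | int | None = None
               ) -> tuple[MsmeSeries, dict]:
    """Bi-exponential MSME decay with optional Gaussian or Rician noise.

    ``noise_sigma`` is in the same units as the signal (absolute);
    ``n_reps`` independent noisy repetitions are averaged, as in the
    two-repetition acquisition the fit consumes.  Rician noise is the
    physically correct magnitude-image model at low SNR.
    """
    if not 0.0 <= myelin_fraction <= 1.0:
        raise ValueError("myelin_fraction must be in [0, 1]")
    if not 0 < t2_fast < t2_slow:
        raise ValueError("require 0 < t2_fast < t2_slow")
    if noise not in ("gaussian", "rician"):
        raise ValueError(f"unknown noise model {noise!r}")
    te = DEFAULT_TE.copy() if te is None else np.asarray(te, dtype=float)
    rng = _rng(seed)
    amp_fast = myelin_fraction * s0
    amp_slow = (1.0 - myelin_fraction) * s0
    clean = biexp_model(te, amp_fast, t2_fast, amp_slow, t2_slow)
    if noise_sigma == 0:
        sig = clean.copy()
    else:
        reps = np.empty((n_reps, te.size))
        for r in range(n_reps):
            if noise == "gaussian":
                reps[r] = clean + rng.normal(0, noise_sigma, te.size)
            else:
                re = clean + rng.normal(0, noise_sigma, te.size)
                im = rng.normal(0, noise_sigma, te.size)
                reps[r] = np.hypot(re, im)
        sig = reps.mean(axis=0)
    sig = np.clip(sig, 0.0, None)
    truth = {"myelin_fraction": myelin_fraction, "t2_fast": t2_fast,
             "t2_slow": t2_slow, "s0": s0, "noise_sigma": noise_sigma,
             "noise": noise, "n_reps": n_reps}
    return MsmeSeries(te, sig, n_reps=n_reps), truth


# ---------------------------------------------------------------------------
# Evoked potentials
# ---------------------------------------------------------------------------

def synth_evoked(epsp_slope: float = 2.0, ps_amplitude: float = 2.0,
                 ps_latency: float = 4.0, ps_halfwidth: float = 1.0,
                 ps_shoulder: float = 0.5, stim_onset: float = 5.0,
                 duration: float = 30.0, dt: float = 0.05,
                 noise_sigma: float = 0.0,
                 seed: np.random.Generator | int | None = None
                 ) -> tuple[SweepTrace, dict]:
    """Stereotyped field potential: EPSP ramp plus a population spike.

    The EPSP rises linearly at ``epsp_slope`` (mV/ms) from the stimulus
    onset, peaks shortly after the spike and decays back to baseline.
    The PS is a piecewise-linear deflection at ``ps_latency`` ms after
    onset: shoulders of height ``ps_shoulder`` flank a trough
    ``ps_amplitude`` mV below the line joining them, so the tangent
    convention recovers the amplitude exactly on the noiseless trace.
    The returned truth carries the analysis windows: the EPSP window
    covers the pre-spike rising phase only.
    """
    if epsp_slope <= 0 or ps_amplitude <= 0:
        raise ValueError("slope and amplitude must be positive")
    if ps_latency - ps_halfwidth <= 0:
        raise ValueError("PS window would overlap the stimulus artifact")
    t = np.arange(0.0, duration + dt / 2, dt)
    rng = _rng(seed)
    rise_end = stim_onset + ps_latency + 2 * ps_halfwidth
    decay_end = min(rise_end + 15.0, duration)
    peak = epsp_slope * (rise_end - stim_onset)
    epsp = np.interp(t, [0, stim_onset, rise_end, decay_end, duration],
                     [0, 0, peak, 0, 0])
    t_ps = stim_onset + ps_latency
    w = ps_halfwidth
    p = ps_shoulder
    ps = np.interp(t, [t_ps - w, t_ps - w / 2, t_ps, t_ps + w / 2, t_ps + w],
                   [0, p, p - ps_amplitude, p, 0])
    ps[(t < t_ps - w) | (t > t_ps + w)] = 0.0
    v = epsp + ps
    if noise_sigma > 0:
        v = v + rng.normal(0, noise_sigma, t.size)
    truth = {
        "epsp_slope": epsp_slope, "ps_amplitude": ps_amplitude,
        "ps_latency": ps_latency, "stim_onset": stim_onset,
        "ps_window": (t_ps - w, t_ps + w),
        "epsp_window": (stim_onset, t_ps - w),
        "noise_sigma": noise_sigma,
    }
    return SweepTrace(t, v, stim_onset=stim_onset), truth


def synth_paired_pulse(ps1_amplitude: float = 2.0, ppr: float = 0.5,
                       seed: np.random.Generator | int | None = None,
                       **kwargs) -> tuple[SweepTrace, SweepTrace, dict]:
    """Two sweeps whose PS amplitudes realise a stated PS2/PS1 ratio."""
    rng = _rng(seed)
    s1, t1 = synth_evoked(ps_amplitude=ps1_amplitude, seed=rng, **kwargs)
    s2, _ = synth_evoked(ps_amplitude=ps1_amplitude * ppr, seed=rng, **kwargs)
    truth = dict(t1, ps1_amplitude=ps1_amplitude, ppr=ppr)
    return s1, s2, truth


def synth_ltp_pair(baseline_ps: float = 2.0, ltp_percent: float = 50.0,
                   seed: np.random.Generator | int | None = None,
                   **kwargs) -> tuple[SweepTrace, SweepTrace, dict]:
    """Baseline and post-induction sweeps realising a stated LTP %."""
    rng = _rng(seed)
    post = baseline_ps * (1 + ltp_percent / 100.0)
    s1, t1 = synth_evoked(ps_amplitude=baseline_ps, seed=rng, **kwargs)
    s2, _ = synth_evoked(ps_amplitude=post, seed=rng, **kwargs)
    truth = dict(t1, baseline_ps=baseline_ps, ltp_percent=ltp_percent)
    return s1, s2, truth


# ---------------------------------------------------------------------------
# Coupled LFP pairs
# ---------------------------------------------------------------------------

def synth_lfp_pair(fs: float = 1000.0, duration: float = 4.0,
                   shared_freq: float = 8.0, gain: float = 1.0,
                   bandwidth: float = 2.0, noise_sigma: float = 1.0,
                   seed: np.random.Generator | int | None = None
                   ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Two LFP-like series sharing a common narrowband component.

    Each channel is independent white noise plus ``gain`` times a common
    narrowband Gaussian process (white noise band-passed around
    ``shared_freq``, unit variance).  A stochastic shared component —
    rather than a deterministic sinusoid — is what makes circular
    time-shift surrogates a valid null: shifting destroys the phase
    co-fluctuations that carry the coupling.  ``gain = 0`` gives an
    uncoupled pair; large gain drives coherence toward 1 in the shared
    band.
    """
    if fs <= 2 * shared_freq:
        raise ValueError("sampling rate must exceed twice the shared "
                         "frequency")
    rng = _rng(seed)
    n = int(round(fs * duration))
    lo = max(shared_freq - bandwidth / 2, 1e-3)
    hi = min(shared_freq + bandwidth / 2, fs / 2 - 1e-3)
    sos = sp_signal.butter(4, [lo, hi], btype="bandpass", fs=fs,
                           output="sos")
    common = sp_signal.sosfiltfilt(sos, rng.standard_normal(n))
    common = common / common.std()
    x = rng.normal(0, noise_sigma, n) + gain * common
    y = rng.normal(0, noise_sigma, n) + gain * common
    truth = {"fs": fs, "shared_freq": shared_freq, "gain": gain,
             "bandwidth": bandwidth, "noise_sigma": noise_sigma, "n": n}
    return x, y, truth


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

# Planted relative FA changes (case vs control).  The target tract
# carries the largest magnitude: 51.5% above the runner-up and 73.9%
# above the mean of the other affected tracts.
DEFAULT_ROI_DELTAS: dict[str, float] = {
    "fornix": -0.100,
    "genu_cc": -0.066,
    "body_cc": -0.060,
    "internal_capsule": -0.058,
    "slf": -0.056,
    "cingulum": -0.055,
    "uncinate": -0.050,
}

_COG_VARS = ("tmt_a", "tmt_b", "nst")
# affine maps from the badness latent to test scales:
# (intercept, scale, sign) — times grow, item counts shrink, with badness
_COG_SCALES = {"tmt_a": (35.0, 10.0, +1.0), "tmt_b": (80.0, 25.0, +1.0),
               "nst": (50.0, 9.0, -1.0)}


def synth_cohort(n_control: int = 35, n_case: int = 48,
                 roi_deltas: dict[str, float] | None = None,
                 fa_ref_mean: float = 0.50, fa_sd: float = 0.04,
                 tau_fa_cognition: float = -0.3,
                 age_effect_fa: float = -0.35, age_effect_cog: float = 0.35,
                 age_mean_control: float = 40.9, age_mean_case: float = 47.5,
                 age_sd: float = 10.0, cog_loading: float = 0.9,
                 seed: np.random.Generator | int | None = None
                 ) -> tuple[pd.DataFrame, dict]:
    """Cohort table with planted group, age and FA-cognition structure.

    FA per ROI is Gaussian around ``fa_ref_mean`` (case means shifted by
    the planted relative change); a latent "badness" factor generates
    the three cognitive scores.  Correlations are induced on a Gaussian
    copula: age loads on both the target-ROI FA (``age_effect_fa``) and
    the latent factor (``age_effect_cog``), and the age-partialled
    dependence between target FA and the latent factor is planted as a
    Kendall tau ``tau_fa_cognition`` via tau = (2/pi) arcsin(rho).
    The affine marginal transforms preserve all rank correlations.
    """
    if n_control < 0 or n_case < 0 or n_control + n_case < 3:
        raise ValueError("need at least 3 subjects in total")
    if 0 < n_control < 3 or 0 < n_case < 3:
        raise ValueError("a non-empty group needs at least 3 subjects")
    if not -1.0 < tau_fa_cognition < 1.0:
        raise ValueError("planted tau must be in (-1, 1)")
    for name, val in (("age_effect_fa", age_effect_fa),
                      ("age_effect_cog", age_effect_cog)):
        if not -1.0 < val < 1.0:
            raise ValueError(f"{name} must be in (-1, 1)")
    rho_partial = np.sin(np.pi * tau_fa_cognition / 2)
    # feasibility of the implied 3x3 latent correlation matrix
    resid = ((1 - age_effect_fa ** 2) * (1 - age_effect_cog ** 2))
    if resid <= 0 or abs(rho_partial) >= 1:
        raise ValueError("infeasible correlation targets (non-PSD)")
    rng = _rng(seed)
    roi_deltas = dict(DEFAULT_ROI_DELTAS if roi_deltas is None
                      else roi_deltas)
    target_roi = max(roi_deltas, key=lambda r: abs(roi_deltas[r]))
    n = n_control + n_case
    group = np.array(["control"] * n_control + ["case"] * n_case)
    is_case = group == "case"

    age = np.where(is_case,
                   rng.normal(age_mean_case, age_sd, n),
                   rng.normal(age_mean_control, age_sd, n))
    # age is centered within group for the latent pathways so the
    # planted group delta is not contaminated by the groups' age gap;
    # within-subject age-FA and age-cognition correlations remain
    z_age = np.empty(n)
    for g in np.unique(group):
        sel = group == g
        z_age[sel] = (age[sel] - age[sel].mean()) / age_sd

    u1 = rng.standard_normal(n)
    u2 = rng.standard_normal(n)
    fa_resid = u1
    g_resid = rho_partial * u1 + np.sqrt(1 - rho_partial ** 2) * u2
    z_fa = age_effect_fa * z_age + np.sqrt(1 - age_effect_fa ** 2) * fa_resid
    g = age_effect_cog * z_age + np.sqrt(1 - age_effect_cog ** 2) * g_resid

    data: dict[str, np.ndarray] = {
        "subject": np.array([f"s{i:03d}" for i in range(n)]),
        "group": group, "age": age,
    }
    for roi, delta in roi_deltas.items():
        mean = fa_ref_mean * np.where(is_case, 1 + delta, 1.0)
        if roi == target_roi:
            fa = mean + fa_sd * z_fa
        else:
            fa = mean + fa_sd * rng.standard_normal(n)
        data[f"fa_{roi}"] = np.clip(fa, 0.0, 1.0)

    lam = cog_loading
    for var in _COG_VARS:
        icept, scale, sign = _COG_SCALES[var]
        noise = rng.standard_normal(n)
        score = lam * g + np.sqrt(1 - lam ** 2) * noise
        data[var] = icept + sign * scale * score
    table = pd.DataFrame(data)
    truth = {
        "roi_deltas": roi_deltas, "target_roi": target_roi,
        "fa_ref_mean": fa_ref_mean, "fa_sd": fa_sd,
        "tau_fa_cognition": tau_fa_cognition,
        "rho_partial": float(rho_partial),
        "age_effect_fa": age_effect_fa, "age_effect_cog": age_effect_cog,
        "cog_loading": cog_loading, "cognitive_vars": list(_COG_VARS),
        "n_control": n_control, "n_case": n_case,
    }
    return table, truth


# ---------------------------------------------------------------------------
# Activation patterns
# ---------------------------------------------------------------------------

def synth_patterns(config: ModelConfig | None = None, n: int = 20,
                   overlap_pairs: bool = False,
                   seed: np.random.Generator | int | None = None
                   ) -> tuple[list[Pattern], dict]:
    """Random activation patterns, optionally as 50%-overlap pairs.

    With ``overlap_pairs`` the second half of the list shares half its
    PFC nodes with the corresponding first-half pattern.
    """
    config = config or ModelConfig()
    rng = _rng(seed)
    patterns: list[Pattern] = []
    half = n // 2
    for i in range(1, n + 1):
        if overlap_pairs and i > half:
            base = patterns[i - half - 1]
            patterns.append(sample_overlap_pair(config, base, rng, i))
        else:
            patterns.append(sample_pattern(config, rng, i))
    truth = {"n": n, "overlap_pairs": overlap_pairs,
             "k_hc": config.k_hc, "k_pfc": config.k_pfc,
             "n_hc": config.n_hc, "n_pfc": config.n_pfc}
    return patterns, truth
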