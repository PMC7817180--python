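"""Psychometric analysis of the head-fixed detection task and proportion
statistics for gap-crossing behavior."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import beta, norm


@dataclass
class PsychometricFit:
    """Maximum-likelihood cumulative-Gaussian fit.

    ``mu`` is the threshold amplitude (the median point of the scaled
    curve, i.e. where the hit rate crosses halfway between the guess rate
    and 1 - lapse); subsequent analyses normalize amplitudes by it.
    """

    mu: float
    sigma: float
    guess: float
    lapse: float
    converged: bool
    log_likelihood: float
    n_trials: int

    def hit_rate(self, amp) -> np.ndarray:
        amp = np.asarray(amp, dtype=float)
        return self.guess + (1 - self.guess - self.lapse) * norm.cdf(
            (amp - self.mu) / self.sigma)

    def normalize(self, amp) -> np.ndarray:
        return np.asarray(amp, dtype=float) / self.mu


def dprime(hit_rate: float, fa_rate: float, n_signal: int, n_noise: int) -> float:
    """Signal-detection sensitivity d' = z(H) - z(FA).

    Rates are clipped to ``[1/(2N), 1 - 1/(2N)]`` with the respective trial
    counts, the standard correction for perfect rates.
    """
    if n_signal <= 0 or n_noise <= 0:
        raise ValueError("trial counts must be positive")
    h = np.clip(hit_rate, 1 / (2 * n_signal), 1 - 1 / (2 * n_signal))
    f = np.clip(fa_rate, 1 / (2 * n_noise), 1 - 1 / (2 * n_noise))
    return float(norm.ppf(h) - norm.ppf(f))


def session_dprime(trials: pd.DataFrame) -> float:
    """Session d' from hit rate on stimulus trials vs false-alarm rate."""
    stim = trials[trials.amplitude > 0]
    catch = trials[trials.amplitude == 0]
    if len(stim) == 0 or len(catch) == 0:
        raise ValueError("need both stimulus and catch trials")
    h = (stim.response == "hit").mean()
    fa = (catch.response == "false_alarm").mean()
    return dprime(h, fa, len(stim), len(catch))


def fit_psychometric(
    trials: pd.DataFrame,
    d_prime_floor: float = 0.8,
    max_guess: float = 0.5,
    max_lapse: float = 0.5,
) -> PsychometricFit:
    """Binomial-ML cumulative-Gaussian fit of hit rate vs amplitude.

    Sessions below the d' floor are excluded before fitting.  Requires at
    least 100 trials spanning at least 4 amplitude levels.  Flat
    (non-identifiable) data yields ``converged=False``.
    """
    t = trials[trials.amplitude > 0].copy()
    if "session_id" in t.columns and "d_prime" in t.columns:
        t = t[t.d_prime > d_prime_floor]
    if len(t) < 100:
        raise ValueError("need >= 100 stimulus trials")
    amps = t.amplitude.to_numpy(dtype=float)
    if np.unique(np.round(amps, 6)).size < 4:
        raise ValueError("need >= 4 distinct amplitude levels")
    hits = (t.response == "hit").to_numpy()

    overall = hits.mean()
    if overall > 0.98 or overall < 0.02:
        return PsychometricFit(np.nan, np.nan, np.nan, np.nan, False, -np.inf, len(t))

    def nll(theta):
        mu, sigma, guess, lapse = theta
        p = guess + (1 - guess - lapse) * norm.cdf((amps - mu) / sigma)
        p = np.clip(p, 1e-9, 1 - 1e-9)
        return -np.sum(np.where(hits, np.log(p), np.log1p(-p)))

    a_lo, a_hi = amps.min(), amps.max()
    x0 = np.array([np.median(amps), 0.2 * (a_hi - a_lo) + 1e-3, 0.05, 0.02])
    res = optimize.minimize(
        nll, x0, method="L-BFGS-B",
        bounds=[(1e-6, 2 * a_hi), (1e-4, a_hi - a_lo + 1.0),
                (0.0, max_guess), (0.0, max_lapse)])
    mu, sigma, guess, lapse = res.x
    # identifiability guard: the curve must actually rise inside the range
    span = (norm.cdf((a_hi - mu) / sigma) - norm.cdf((a_lo - mu) / sigma))
    converged = bool(res.success) and span > 0.1 and mu > 0
    return PsychometricFit(float(mu), float(sigma), float(guess), float(lapse),
                           converged, -float(res.fun), len(t))


# named trial-exclusion rules; each maps a trials frame to a keep-mask
def _rule_dprime(t, floor=1.2):
    if "d_prime" not in t.columns:
        return np.ones(len(t), dtype=bool)
    return (t.d_prime >= floor).to_numpy()


def _rule_early_response(t, min_rt_ms=50.0):
    rt = t.reaction_time_ms.to_numpy(dtype=float)
    return ~(np.isfinite(rt) & (rt < min_rt_ms))


def _rule_late_deviant(t, max_ms=400.0):
    dt = t.deviant_time_ms.to_numpy(dtype=float)
    return ~(np.isfinite(dt) & (dt > max_ms))


def _rule_subthreshold(t, threshold_amp=None, band=0.6):
    if threshold_amp is None:
        raise ValueError("subthreshold rule requires threshold_amp")
    a = t.amplitude.to_numpy(dtype=float)
    return (a > 0) & (a < band * threshold_amp)


RULES = {
    "d_prime_floor": _rule_dprime,
    "early_response": _rule_early_response,
    "late_deviant": _rule_late_deviant,
    "subthreshold_band": _rule_subthreshold,
}


def filter_trials(trials: pd.DataFrame, rules, **kwargs):
    """Apply named exclusion rules; returns (filtered, audit dict).

    Rules (applied in order): ``d_prime_floor`` (session d' >= 1.2),
    ``early_response`` (drop responses within 50 ms of stimulus onset),
    ``late_deviant`` (drop deviants later than 400 ms),
    ``subthreshold_band`` (keep amplitudes below 60% of threshold;
    pass ``threshold_amp=``).
    """
    keep = np.ones(len(trials), dtype=bool)
    audit = {}
    for name in rules:
        fn = RULES.get(name)
        if fn is None:
            raise KeyError(f"unknown filter rule {name!r}")
        rule_kwargs = {k: v for k, v in kwargs.items()
                       if k in fn.__code__.co_varnames}
        mask = fn(trials, **rule_kwargs)
        audit[name] = int(np.sum(keep & ~mask))
        keep &= mask
    return trials[keep].reset_index(drop=True), audit


def hit_rate_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    a = 1 - level
    lo = 0.0 if k == 0 else float(beta.ppf(a / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.ppf(1 - a / 2, k + 1, n - k))
    return lo, hi


def compare_rates_bootstrap(
    k_a: int, n_a: int, k_b: int, n_b: int,
    n_boot: int = 10000, seed=0,
) -> float:
    """Two-sided bootstrap p-value for a difference of binomial rates.

    Resamples each group's observed rate ``n_boot`` times and evaluates the
    sign of the rate difference (add-one estimator); used for the
    deviant-benefit and gap-crossing probability contrasts.
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("trial counts must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pa = rng.binomial(n_a, k_a / n_a, size=n_boot) / n_a
    pb = rng.binomial(n_b, k_b / n_b, size=n_boot) / n_b
    d = pa - pb
    p_pos = (1 + np.sum(d <= 0)) / (1 + n_boot)
    p_neg = (1 + np.sum(d >= 0)) / (1 + n_boot)
    return float(min(1.0, 2 * min(p_pos, p_neg)))


def deviant_benefit(
    trials: pd.DataFrame,
    fit: PsychometricFit | None = None,
    band: float = 0.6,
    n_boot: int = 10000,
    seed=0,
) -> dict:
    """Detection benefit of deviants for sub-threshold stimuli.

    Filters to amplitudes below ``band`` x threshold (after the standard
    exclusion rules) and compares hit rates between deviant-containing and
    baseline trials with the binomial bootstrap.
    """
    if fit is None:
        fit = fit_psychometric(trials)
    filtered, audit = filter_trials(
        trials, ["early_response", "late_deviant", "subthreshold_band"],
        threshold_amp=fit.mu, band=band)
    dev = filtered[filtered.deviant_present]
    base = filtered[~filtered.deviant_present]
    k_a, n_a = int((dev.response == "hit").sum()), len(dev)
    k_b, n_b = int((base.response == "hit").sum()), len(base)
    p = compare_rates_bootstrap(k_a, n_a, k_b, n_b, n_boot=n_boot, seed=seed)
    return {"hit_rate_deviant": k_a / n_a if n_a else np.nan,
            "hit_rate_baseline": k_b / n_b if n_b else np.nan,
            "benefit": (k_a / n_a - k_b / n_b) if n_a and n_b else np.nan,
            "ci_deviant": hit_rate_ci(k_a, n_a) if n_a else (np.nan, np.nan),
            "ci_baseline": hit_rate_ci(k_b, n_b) if n_b else (np.nan, np.nan),
            "p": p, "n": (n_a, n_b), "audit": audit,
            "threshold_amp": fit.mu}
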