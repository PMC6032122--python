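"""Maximum-likelihood psychometric fitting and time-resolved thresholds.

The psychometric model is a 2AFC logistic with a guessing floor of 0.5
and a lapse rate ``lam`` capping asymptotic performance at ``1 - lam/2``::

    p(correct) = 0.5 + 0.5 * (1 - lam) / (1 + exp((mu - c) / s))

Contrast ``c`` is handled in log10 units throughout (the staircases step
in log units); ``mu`` is therefore the log10 contrast at which
performance reaches 75% correct when ``lam`` is 0, and linear-contrast
thresholds are ``10**mu``.  Sensitivity is the reciprocal of the linear
threshold, and the log sensitivity ratio

    SR = log10(sensitivity / baseline sensitivity) = -(mu - mu_baseline)

is negative under suppression (threshold elevated) and positive under
facilitation, matching the sign convention of the gain model.

Protocol: one global joint fit estimates a single lapse rate and per
spatial-frequency slopes; those are then frozen, and every time-binned
fit frees only ``mu``.  All optimisation is deterministic (fixed grid
multi-start + bounded Brent / L-BFGS-B), so fits reproduce without seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "PsychometricParams", "GlobalFit", "predict", "neg_log_likelihood",
    "fit_mu", "fit_ml", "global_fit", "bin_by_latency", "baseline_trials",
    "sensitivity_timecourse", "window_csf", "orientation_partition",
    "SUPPRESSION_WINDOW", "FACILITATION_WINDOW",
]

# Analysis windows: suppression 0.1 s before to 0.05 s after onset,
# facilitation 0.05-0.2 s after onset (both 0.15 s long).
SUPPRESSION_WINDOW = (-0.1, 0.05)
FACILITATION_WINDOW = (0.05, 0.2)

# Exclusion zone (in tau = t_stim - t_onset) around every microsaccade
# for a trial to count as baseline: stimulus must fall >0.1 s before or
# >0.5 s after each event.
BASELINE_EXCLUDE = (-0.1, 0.5)


@dataclass(frozen=True)
class PsychometricParams:
    """Threshold, slope and lapse of the 2AFC logistic (log10-contrast units)."""

    mu: float
    s: float
    lam: float = 0.0

    def __post_init__(self):
        if self.s <= 0:
            raise ValueError("slope s must be positive")
        if not (0.0 <= self.lam < 1.0):
            raise ValueError("lapse rate must be in [0, 1)")


@dataclass
class GlobalFit:
    """Joint-fit result: shared lapse plus per-spatial-frequency (mu, s)."""

    lam: float
    mu: dict = field(default_factory=dict)     # sf -> mu (log10 contrast)
    s: dict = field(default_factory=dict)      # sf -> slope
    log_likelihood: float = np.nan

    def params(self, sf: float) -> PsychometricParams:
        return PsychometricParams(mu=self.mu[sf], s=self.s[sf], lam=self.lam)


def predict(contrast, mu: float, s: float, lam: float = 0.0):
    """Probability correct of the 2AFC logistic at ``contrast`` (same units as mu)."""
    if s <= 0:
        raise ValueError("slope s must be positive")
    c = np.asarray(contrast, dtype=float)
    p = 0.5 + 0.5 * (1.0 - lam) / (1.0 + np.exp((mu - c) / s))
    return p if p.ndim else float(p)


def neg_log_likelihood(c, y, mu, s, lam):
    """Bernoulli negative log-likelihood of correctness ``y`` at contrasts ``c``."""
    p = 0.5 + 0.5 * (1.0 - lam) / (1.0 + np.exp((mu - np.asarray(c)) / s))
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    y = np.asarray(y, dtype=float)
    return -float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def _mu_bounds(c, s):
    lo = float(np.min(c)) - 6.0 * s
    hi = float(np.max(c)) + 6.0 * s
    return lo, hi


def fit_mu(c, y, s: float, lam: float, bounds=None):
    """Threshold-only ML fit with slope and lapse frozen.

    Deterministic: coarse grid over the contrast range, then bounded
    Brent refinement around the best grid point.  Returns
    ``(mu_hat, log_likelihood, flag)`` where flag is '' or 'boundary'
    (all-correct / all-wrong style data pushing mu to the search bound).
    """
    c = np.asarray(c, dtype=float)
    y = np.asarray(y, dtype=float)
    if c.size == 0:
        raise ValueError("no trials to fit")
    lo, hi = bounds if bounds is not None else _mu_bounds(c, s)
    grid = np.linspace(lo, hi, 41)
    nll_grid = [neg_log_likelihood(c, y, m, s, lam) for m in grid]
    k = int(np.argmin(nll_grid))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda m: neg_log_likelihood(c, y, m, s, lam),
        bounds=(a, b), method="bounded", options={"xatol": 1e-7},
    )
    mu_hat = float(res.x)
    flag = "boundary" if (mu_hat - lo < 1e-3 * (hi - lo) or hi - mu_hat < 1e-3 * (hi - lo)) else ""
    return mu_hat, -float(res.fun), flag


def fit_ml(c, y, free=("mu",), fixed=None):
    """ML fit of the logistic with an arbitrary subset of free parameters.

    ``fixed`` supplies values for the frozen parameters (and starting
    values for free ones if given).  Returns ``(PsychometricParams,
    log_likelihood, flag)``.
    """
    fixed = dict(fixed or {})
    c = np.asarray(c, dtype=float)
    y = np.asarray(y, dtype=float)
    free = tuple(free)
    if set(free) == {"mu"}:
        s = fixed["s"]
        lam = fixed.get("lam", 0.0)
        mu_hat, ll, flag = fit_mu(c, y, s, lam)
        return PsychometricParams(mu_hat, s, lam), ll, flag
    if c.size and (np.unique(c).size < 2 or np.unique(y).size < 2) and len(free) > 1:
        # degenerate design for a multi-parameter fit
        flag = "boundary"
    else:
        flag = ""
    span = max(float(np.ptp(c)), 0.05)
    defaults = {"mu": float(np.median(c)), "s": 0.25 * span, "lam": 0.03}
    x0, lo, hi, names = [], [], [], []
    bounds_map = {
        "mu": _mu_bounds(c, fixed.get("s", defaults["s"])),
        "s": (1e-3, 5.0 * span),
        "lam": (0.0, 0.4),
    }
    for name in ("mu", "s", "lam"):
        if name in free:
            names.append(name)
            x0.append(fixed.get(name, defaults[name]))
            b = bounds_map[name]
            lo.append(b[0])
            hi.append(b[1])

    def unpack(x):
        p = dict(fixed)
        p.update(dict(zip(names, x)))
        return p

    def nll(x):
        p = unpack(x)
        return neg_log_likelihood(c, y, p["mu"], max(p["s"], 1e-6), p["lam"])

    res = optimize.minimize(
        nll, np.asarray(x0), method="L-BFGS-B", bounds=list(zip(lo, hi)),
    )
    if not res.success and not flag:
        flag = "no-convergence"
    p = unpack(res.x)
    for name, b in bounds_map.items():
        if name in names and (abs(p[name] - b[0]) < 1e-9 or abs(p[name] - b[1]) < 1e-9):
            flag = flag or "boundary"
    return PsychometricParams(p["mu"], max(p["s"], 1e-6), p["lam"]), -float(res.fun), flag


def global_fit(trials: pd.DataFrame, sfs=None) -> GlobalFit:
    """Joint ML fit over all spatial frequencies with one shared lapse.

    mu and s vary per spatial frequency; the fitted lam and s are then
    frozen for all time-binned threshold fits.
    """
    sfs = sorted(trials["sf_cpd"].unique()) if sfs is None else list(sfs)
    groups = []
    for sf in sfs:
        sub = trials[trials["sf_cpd"] == sf]
        if len(sub) == 0:
            raise ValueError(f"no trials at spatial frequency {sf}")
        groups.append((sub["log10_contrast"].to_numpy(),
                       sub["correct"].to_numpy(dtype=float)))

    # starting values: per-sf threshold-only prefits at a plausible slope
    x0, bounds = [], []
    for c, y in groups:
        mu0, _, _ = fit_mu(c, y, s=0.08, lam=0.05)
        span = max(float(np.ptp(c)), 0.05)
        x0 += [mu0, 0.08]
        bounds += [(_mu_bounds(c, 0.2)), (5e-3, 2.0 * span)]
    x0.append(0.05)
    bounds.append((0.0, 0.4))

    def nll(x):
        lam = x[-1]
        total = 0.0
        for i, (c, y) in enumerate(groups):
            total += neg_log_likelihood(c, y, x[2 * i], max(x[2 * i + 1], 1e-6), lam)
        return total

    res = optimize.minimize(nll, np.asarray(x0), method="L-BFGS-B", bounds=bounds)
    out = GlobalFit(lam=float(res.x[-1]), log_likelihood=-float(res.fun))
    for i, sf in enumerate(sfs):
        out.mu[sf] = float(res.x[2 * i])
        out.s[sf] = float(max(res.x[2 * i + 1], 1e-6))
    return out


def bin_by_latency(trials: pd.DataFrame, width: float = 0.1, step: float = 0.002,
                   trange=(-0.1, 0.4)):
    """Sliding latency bins: center tau_c keeps trials with
    tau in [tau_c - width/2, tau_c + width/2).  Yields (tau_c, subset)."""
    lo, hi = trange
    if hi < lo:
        return
    tau = trials["tau_s"].to_numpy()
    centers = np.arange(lo, hi + 0.5 * step, step)
    for tc in centers:
        m = (tau >= tc - width / 2) & (tau < tc + width / 2)
        yield float(tc), trials[m]


def baseline_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Trials whose stimulus fell >0.1 s before or >0.5 s after every
    microsaccade (no onset inside the perisaccadic zone).

    Uses the ``is_baseline`` column attached by the preprocessing step
    when present (which checks *every* event); otherwise falls back to
    the nearest-event latency alone.
    """
    if "is_baseline" in trials.columns:
        return trials[trials["is_baseline"].astype(bool)]
    tau = trials["tau_s"].to_numpy()
    keep = (tau <= BASELINE_EXCLUDE[0]) | (tau >= BASELINE_EXCLUDE[1])
    return trials[keep]


LOW_N = 30  # bins with fewer trials are flagged, not suppressed


def _matched_baseline_mu(bin_trials, base, sf, gf, rng, n_reps=50):
    from .resample import subject_match  # local import to avoid a cycle

    def fit_fn(df):
        mu, _, _ = fit_mu(df["log10_contrast"].to_numpy(),
                          df["correct"].to_numpy(dtype=float),
                          s=gf.s[sf], lam=gf.lam)
        return mu

    mb = subject_match(base, bin_trials, fit_fn, n_reps=n_reps, rng=rng)
    return mb.mean_threshold


def sensitivity_timecourse(trials: pd.DataFrame, gf: GlobalFit,
                           width: float = 0.1, step: float = 0.002,
                           trange=(-0.1, 0.4), rng=None,
                           n_matched: int = 50) -> pd.DataFrame:
    """Per-(latency bin, spatial frequency) thresholds and log
    sensitivity ratios against subject-matched baselines.

    SR = -(mu_bin - mu_baseline) in log10 units: negative = suppression.
    """
    rng = np.random.default_rng(rng)
    rows = []
    sfs = sorted(trials["sf_cpd"].unique())
    base_all = baseline_trials(trials)
    for sf in sfs:
        sub = trials[trials["sf_cpd"] == sf]
        base = base_all[base_all["sf_cpd"] == sf]
        if len(base) == 0:
            raise ValueError(f"no baseline trials at sf={sf}")
        mu_base_plain, _, _ = fit_mu(base["log10_contrast"].to_numpy(),
                                     base["correct"].to_numpy(dtype=float),
                                     s=gf.s[sf], lam=gf.lam)
        for tc, bin_trials in bin_by_latency(sub, width, step, trange):
            n = len(bin_trials)
            if n == 0:
                rows.append(dict(tau_s=tc, sf_cpd=sf, mu=np.nan, sensitivity=np.nan,
                                 sr_log10=np.nan, n_trials=0, low_n=True))
                continue
            mu_bin, _, _ = fit_mu(bin_trials["log10_contrast"].to_numpy(),
                                  bin_trials["correct"].to_numpy(dtype=float),
                                  s=gf.s[sf], lam=gf.lam)
            if n_matched > 0 and trials["subject"].nunique() > 1:
                mu_base = _matched_baseline_mu(bin_trials, base, sf, gf, rng,
                                               n_reps=n_matched)
            else:
                mu_base = mu_base_plain
            rows.append(dict(
                tau_s=tc, sf_cpd=sf, mu=10.0 ** mu_bin,
                sensitivity=10.0 ** -mu_bin,
                sr_log10=-(mu_bin - mu_base),
                n_trials=n, low_n=n < LOW_N,
            ))
    return pd.DataFrame(rows)


def window_csf(trials: pd.DataFrame, window, gf: GlobalFit, rng=None,
               n_matched: int = 50) -> pd.DataFrame:
    """Contrast sensitivity function inside a latency window, with
    subject-matched baseline thresholds per spatial frequency."""
    rng = np.random.default_rng(rng)
    lo, hi = window
    rows = []
    base_all = baseline_trials(trials)
    for sf in sorted(trials["sf_cpd"].unique()):
        sub = trials[(trials["sf_cpd"] == sf)
                     & (trials["tau_s"] >= lo) & (trials["tau_s"] < hi)]
        base = base_all[base_all["sf_cpd"] == sf]
        if len(sub) == 0 or len(base) == 0:
            rows.append(dict(sf_cpd=sf, mu=np.nan, mu_baseline=np.nan,
                             sensitivity=np.nan, sr_log10=np.nan, n_trials=len(sub)))
            continue
        mu_w, _, _ = fit_mu(sub["log10_contrast"].to_numpy(),
                            sub["correct"].to_numpy(dtype=float),
                            s=gf.s[sf], lam=gf.lam)
        if n_matched > 0 and trials["subject"].nunique() > 1:
            mu_b = _matched_baseline_mu(sub, base, sf, gf, rng, n_reps=n_matched)
        else:
            mu_b, _, _ = fit_mu(base["log10_contrast"].to_numpy(),
                                base["correct"].to_numpy(dtype=float),
                                s=gf.s[sf], lam=gf.lam)
        rows.append(dict(sf_cpd=sf, mu=10.0 ** mu_w, mu_baseline=10.0 ** mu_b,
                         sensitivity=10.0 ** -mu_w, sr_log10=-(mu_w - mu_b),
                         n_trials=len(sub)))
    return pd.DataFrame(rows)


def axial_difference(stim_orientation_deg, event_direction_deg):
    """Fold the angle between stimulus orientation and microsaccade
    direction into [0, 90] treating both as axial (mod 180)."""
    d = np.abs(np.asarray(stim_orientation_deg, float)
               - np.asarray(event_direction_deg, float)) % 180.0
    return np.where(d > 90.0, 180.0 - d, d)


def orientation_partition(trials: pd.DataFrame, gf: GlobalFit,
                          window=SUPPRESSION_WINDOW, n_bins: int = 5,
                          rng=None, n_matched: int = 50,
                          pool_sfs: bool = False) -> pd.DataFrame:
    """Thresholds in the suppression window partitioned by the axial
    angle between microsaccade direction and stimulus orientation
    (five 18-degree bins from parallel to orthogonal).

    Requires an ``event_direction_deg`` column (direction of the
    nearest microsaccade).  With ``pool_sfs`` the partition is computed
    on all spatial frequencies together (slope/lapse from the lowest sf).
    """
    rng = np.random.default_rng(rng)
    lo, hi = window
    sub = trials[(trials["tau_s"] >= lo) & (trials["tau_s"] < hi)].copy()
    sub["delta_deg"] = axial_difference(sub["stim_orientation_deg"],
                                        sub["event_direction_deg"])
    edges = np.linspace(0.0, 90.0, n_bins + 1)
    base_all = baseline_trials(trials)
    rows = []
    sf_groups = [None] if pool_sfs else sorted(sub["sf_cpd"].unique())
    for sf in sf_groups:
        if sf is None:
            s_sub, base = sub, base_all
            s_fit = gf.s[min(gf.s)]
        else:
            s_sub = sub[sub["sf_cpd"] == sf]
            base = base_all[base_all["sf_cpd"] == sf]
            s_fit = gf.s[sf]
        for i in range(n_bins):
            m = (s_sub["delta_deg"] >= edges[i]) & (s_sub["delta_deg"] <= edges[i + 1]
                                                    if i == n_bins - 1
                                                    else s_sub["delta_deg"] < edges[i + 1])
            bt = s_sub[m]
            center = 0.5 * (edges[i] + edges[i + 1])
            if len(bt) == 0:
                rows.append(dict(sf_cpd=sf, delta_center_deg=center, mu=np.nan,
                                 sr_log10=np.nan, n_trials=0))
                continue
            mu_bin, _, _ = fit_mu(bt["log10_contrast"].to_numpy(),
                                  bt["correct"].to_numpy(dtype=float),
                                  s=s_fit, lam=gf.lam)
            if n_matched > 0 and trials["subject"].nunique() > 1 and sf is not None:
                mu_b = _matched_baseline_mu(bt, base, sf, gf, rng, n_reps=n_matched)
            else:
                mu_b, _, _ = fit_mu(base["log10_contrast"].to_numpy(),
                                    base["correct"].to_numpy(dtype=float),
                                    s=s_fit, lam=gf.lam)
            rows.append(dict(sf_cpd=sf, delta_center_deg=center, mu=10.0 ** mu_bin,
                             sr_log10=-(mu_bin - mu_b), n_trials=len(bt)))
    return pd.DataFrame(rows)
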