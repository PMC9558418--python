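"""Three-parameter log-logistic dose-response fitting and ED50 comparison.

Model (lower asymptote fixed at 0)::

    f(x) = d / (1 + exp(b * (ln x - ln e)))

with upper asymptote ``d``, slope ``b`` (b > 0 means response falls with
dose) and ED50 ``e``.  ``f(e) = d / 2`` exactly.  Fitting is least squares
on ln-dose; vehicle rows (dose 0) are excluded from the fit and used only
for normalization checks.  Confidence intervals come from a nonparametric
bootstrap over replicates, stratified by dose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseData",
    "LL3Fit",
    "ll3",
    "fit_ll3",
    "ed50_fold_change",
]


def ll3(x, d, b, e):
    """Three-parameter log-logistic response at dose ``x`` (x > 0)."""
    x = np.asarray(x, dtype=float)
    return d / (1.0 + np.exp(b * (np.log(x) - np.log(e))))


@dataclass
class DoseResponseData:
    """Dose-response measurements; responses are fractions of vehicle control.

    Vehicle rows (dose exactly 0) are retained but excluded from fitting.
    At least 3 distinct positive doses are required (one per parameter).
    """

    doses: np.ndarray
    responses: np.ndarray
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.doses.shape != self.responses.shape:
            raise ValueError("doses and responses must have the same shape")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")
        if np.any(self.doses < 0):
            raise ValueError("doses must be >= 0 (0 = vehicle)")
        n_distinct = len(np.unique(self.doses[self.doses > 0]))
        if n_distinct < 3:
            raise ValueError(
                f"need >= 3 distinct positive doses to identify 3 parameters, got {n_distinct}"
            )

    @property
    def positive(self) -> tuple[np.ndarray, np.ndarray]:
        mask = self.doses > 0
        return self.doses[mask], self.responses[mask]


@dataclass
class LL3Fit:
    d: float
    b: float
    e: float
    converged: bool
    censored: bool
    rss: float
    n_boot: int = 0
    ci_d: tuple[float, float] | None = None
    ci_b: tuple[float, float] | None = None
    ci_e: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for lo_hi in (self.ci_d, self.ci_b, self.ci_e):
            if lo_hi is not None and lo_hi[0] > lo_hi[1]:
                raise ValueError("CI bounds must be ordered")

    def predict(self, x):
        return ll3(x, self.d, self.b, self.e)


def _fit_core(doses: np.ndarray, responses: np.ndarray):
    """Bounded least-squares fit; returns (d, b, e, rss, success, e_at_bound)."""
    logx = np.log(doses)
    d0 = float(responses.max())
    # e0: dose whose mean response is nearest half the top response
    uniq = np.unique(doses)
    means = np.array([responses[doses == u].mean() for u in uniq])
    e0 = float(uniq[np.argmin(np.abs(means - d0 / 2.0))])
    b0 = 1.0

    e_hi = 1e3 * doses.max()
    d_hi = 1.5 * max(d0, 1e-9)
    lo = np.array([1e-9, 0.1, 1e-9])
    hi = np.array([d_hi, 20.0, e_hi])
    x0 = np.clip(np.array([d0, b0, e0]), lo, hi)

    def resid(theta):
        d, b, e = theta
        return d / (1.0 + np.exp(b * (logx - np.log(e)))) - responses

    res = least_squares(resid, x0, bounds=(lo, hi), method="trf")
    d, b, e = res.x
    rss = float(np.sum(res.fun**2))
    e_at_bound = e >= 0.999 * e_hi
    return float(d), float(b), float(e), rss, bool(res.success), e_at_bound


def fit_ll3(
    data: DoseResponseData,
    n_boot: int = 0,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> LL3Fit:
    """Fit the 3-parameter log-logistic model.

    With ``n_boot > 0`` a nonparametric bootstrap over replicates (resampled
    within each dose, seeded) yields percentile confidence intervals.

    A curve with no measurable kill (response not falling with dose) is
    flagged: ``censored`` is set when the estimated ED50 exceeds the highest
    tested dose, and ``converged`` is cleared when the estimate ran into the
    optimizer bound — the ED50 should then be read as "> max dose".
    """
    doses, responses = data.positive
    d, b, e, rss, success, e_at_bound = _fit_core(doses, responses)
    censored = e > doses.max()
    fit = LL3Fit(
        d=d, b=b, e=e,
        converged=success and not e_at_bound and not censored,
        censored=censored,
        rss=rss,
        n_boot=n_boot,
    )
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        uniq = np.unique(doses)
        groups = [np.flatnonzero(doses == u) for u in uniq]
        boot = np.empty((n_boot, 3))
        for i in range(n_boot):
            idx = np.concatenate(
                [rng.choice(g, size=len(g), replace=True) for g in groups]
            )
            try:
                bd, bb, be, *_ = _fit_core(doses[idx], responses[idx])
            except Exception:  # pragma: no cover - degenerate resample
                bd, bb, be = d, b, e
            boot[i] = bd, bb, be
        q = 100 * np.array([(1 - ci_level) / 2, 1 - (1 - ci_level) / 2])
        lo_d, hi_d = np.percentile(boot[:, 0], q)
        lo_b, hi_b = np.percentile(boot[:, 1], q)
        lo_e, hi_e = np.percentile(boot[:, 2], q)
        fit.ci_d = (float(lo_d), float(hi_d))
        fit.ci_b = (float(lo_b), float(hi_b))
        fit.ci_e = (float(lo_e), float(hi_e))
    return fit


def _geomean(values: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(values))))


def ed50_fold_change(
    fits_a: list[LL3Fit],
    fits_b: list[LL3Fit],
    n_boot: int = 1000,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> tuple[float, tuple[float, float] | None]:
    """Geometric-mean ED50 ratio between two groups of fitted curves.

    Returns ``geomean(e in B) / geomean(e in A)``; with sensitive group A
    and resistant group B the ratio reads "B needs N-fold more drug".
    Censored fits are excluded with a warning; a group with no usable fit is
    an error.  The CI resamples fits within each group (seeded).
    """

    def usable(fits, name):
        kept = [f.e for f in fits if f.converged and not f.censored]
        dropped = len(fits) - len(kept)
        if dropped:
            warnings.warn(
                f"excluded {dropped} censored/non-converged fit(s) from group {name}",
                stacklevel=3,
            )
        if not kept:
            raise ValueError(f"no converged, uncensored fits in group {name}")
        return np.array(kept)

    e_a = usable(fits_a, "A")
    e_b = usable(fits_b, "B")
    ratio = _geomean(e_b) / _geomean(e_a)
    ci = None
    if n_boot > 0 and (len(e_a) > 1 or len(e_b) > 1):
        rng = np.random.default_rng(seed)
        samples = np.empty(n_boot)
        for i in range(n_boot):
            ra = rng.choice(e_a, size=len(e_a), replace=True)
            rb = rng.choice(e_b, size=len(e_b), replace=True)
            samples[i] = _geomean(rb) / _geomean(ra)
        q = 100 * np.array([(1 - ci_level) / 2, 1 - (1 - ci_level) / 2])
        lo, hi = np.percentile(samples, q)
        ci = (float(lo), float(hi))
    return ratio, ci
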