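"""Single-hit limiting-dilution analysis (LDA).

Dose-response tables from limiting-dilution transplants (dose = cells per
animal, n tested, n responding) are fit under the single-hit Poisson
model: an animal responds iff it received at least one functional cell, so
P(response | dose d) = 1 - exp(-f * d) where f is the frequency of
functional cells.  This is a binomial GLM with a complementary log-log
link and log-dose offset; the intercept is log f.  The MLE is found on
beta = log f; confidence intervals are Wald on beta by default, switching
to profile likelihood when any dose group is saturated (all-positive or
all-negative), where the curvature-based Wald interval is unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._utils import ValidationError

__all__ = ["LdaResult", "validate_lda_table", "lda_frequency", "compare_frequencies"]

_BETA_LO, _BETA_HI = -40.0, 10.0  # search window for log-frequency


@dataclass
class LdaResult:
    """Estimated frequency of functional cells with confidence interval."""

    frequency: float
    ci_low: float
    ci_high: float
    conf_level: float
    flags: list[str] = field(default_factory=list)
    #: True when the MLE itself sits at a boundary (all animals negative or
    #: all positive overall); saturated single dose groups only change the
    #: CI method and leave this False.
    boundary: bool = False

    @property
    def one_in(self) -> float:
        """Frequency reported as '1 in N' (rounded up, conservative)."""
        if self.frequency <= 0:
            return float("inf")
        return float(np.ceil(1.0 / self.frequency))


def validate_lda_table(table: pd.DataFrame) -> pd.DataFrame:
    for col in ("dose", "n_tested", "n_positive"):
        if col not in table.columns:
            raise ValidationError(f"LDA table missing column {col!r}")
    if len(table) == 0:
        raise ValidationError("LDA table is empty")
    if (table["dose"] <= 0).any():
        raise ValidationError("doses must be > 0")
    if (table["n_tested"] <= 0).any():
        raise ValidationError("n_tested must be > 0")
    if ((table["n_positive"] < 0) | (table["n_positive"] > table["n_tested"])).any():
        raise ValidationError("need 0 <= n_positive <= n_tested")
    return table


def _loglik(beta: float, d: np.ndarray, n: np.ndarray, k: np.ndarray) -> float:
    """Binomial log-likelihood at log-frequency beta (constants dropped)."""
    lam = np.exp(beta) * d
    # log(1 - exp(-lam)) computed stably
    log_p = np.log(-np.expm1(-lam))
    return float(np.sum(k * log_p - (n - k) * lam))


def _mle_beta(d: np.ndarray, n: np.ndarray, k: np.ndarray) -> float:
    res = optimize.minimize_scalar(
        lambda b: -_loglik(b, d, n, k),
        bounds=(_BETA_LO, _BETA_HI),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)


def _profile_ci(beta_hat: float, d, n, k, conf_level: float) -> tuple[float, float]:
    ll_max = _loglik(beta_hat, d, n, k)
    crit = stats.chi2.ppf(conf_level, df=1) / 2.0

    def g(b: float) -> float:
        return ll_max - _loglik(b, d, n, k) - crit

    lo = _BETA_LO if g(_BETA_LO) < 0 else optimize.brentq(g, _BETA_LO, beta_hat)
    hi = _BETA_HI if g(_BETA_HI) < 0 else optimize.brentq(g, beta_hat, _BETA_HI)
    return lo, hi


def lda_frequency(table: pd.DataFrame, conf_level: float = 0.95) -> LdaResult:
    """Maximum-likelihood frequency of functional cells from a dose table.

    Boundary cases: all animals negative gives f = 0 with a one-sided
    upper bound (the frequency at which 'all negative' has probability
    1 - conf_level); all animals positive gives a finite lower bound with
    the point estimate and upper bound flagged as boundary values.
    """
    table = validate_lda_table(table)
    if not 0 < conf_level < 1:
        raise ValidationError("conf_level must be in (0, 1)")
    d = table["dose"].to_numpy(dtype=float)
    n = table["n_tested"].to_numpy(dtype=float)
    k = table["n_positive"].to_numpy(dtype=float)
    alpha = 1.0 - conf_level

    if k.sum() == 0:
        # P(all negative | f) = exp(-f * sum(n_i d_i))
        upper = -np.log(alpha) / float((n * d).sum())
        return LdaResult(0.0, 0.0, upper, conf_level,
                         flags=["all animals negative: frequency 0, one-sided upper bound"],
                         boundary=True)
    if (k == n).all():
        beta_hat = _mle_beta(d, n, k)  # runs to the upper search bound
        lo, _ = _profile_ci(beta_hat, d, n, k, conf_level)
        return LdaResult(float(np.exp(beta_hat)), float(np.exp(lo)), float("inf"),
                         conf_level,
                         flags=["all animals positive: only the lower bound is informative"],
                         boundary=True)

    beta_hat = _mle_beta(d, n, k)
    saturated = ((k == 0) | (k == n)).any()
    if saturated:
        lo, hi = _profile_ci(beta_hat, d, n, k, conf_level)
        flags = ["saturated dose group: profile-likelihood CI"]
    else:
        # Wald on beta: observed information via numerical curvature
        h = 1e-5
        info = -(_loglik(beta_hat + h, d, n, k) - 2 * _loglik(beta_hat, d, n, k)
                 + _loglik(beta_hat - h, d, n, k)) / h**2
        if info <= 0:
            lo, hi = _profile_ci(beta_hat, d, n, k, conf_level)
            flags = ["non-positive curvature: profile-likelihood CI"]
        else:
            z = stats.norm.ppf(1 - alpha / 2)
            se = 1.0 / np.sqrt(info)
            lo, hi = beta_hat - z * se, beta_hat + z * se
            flags = []
    return LdaResult(float(np.exp(beta_hat)), float(np.exp(lo)), float(np.exp(hi)),
                     conf_level, flags=flags)


def compare_frequencies(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    conf_level: float = 0.95,
) -> dict:
    """Frequency ratio f_a / f_b with a likelihood-ratio test of f_a = f_b.

    Returns a dict with keys ratio, p, frequency_a, frequency_b, flags.
    When either frequency sits at a boundary (all positive / all negative)
    the ratio and p-value are omitted and flagged instead.
    """
    res_a = lda_frequency(table_a, conf_level)
    res_b = lda_frequency(table_b, conf_level)
    out = {"frequency_a": res_a.frequency, "frequency_b": res_b.frequency,
           "ratio": None, "p": None, "flags": []}
    if res_a.boundary or res_b.boundary:
        out["flags"] = ["boundary estimate in at least one group; ratio/test omitted"]
        return out
    arrays = []
    for t in (table_a, table_b):
        t = validate_lda_table(t)
        arrays.append((t["dose"].to_numpy(float), t["n_tested"].to_numpy(float),
                       t["n_positive"].to_numpy(float)))
    (da, na, ka), (db, nb, kb) = arrays
    ll_sep = (_loglik(np.log(res_a.frequency), da, na, ka)
              + _loglik(np.log(res_b.frequency), db, nb, kb))
    d0 = np.concatenate([da, db])
    n0 = np.concatenate([na, nb])
    k0 = np.concatenate([ka, kb])
    ll_null = _loglik(_mle_beta(d0, n0, k0), d0, n0, k0)
    lr = max(0.0, 2.0 * (ll_sep - ll_null))
    out["ratio"] = res_a.frequency / res_b.frequency
    out["p"] = float(stats.chi2.sf(lr, df=1))
    return out
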