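"""Parameter distributions fitted to published summary statistics.

The probabilistic sensitivity analysis draws every uncertain input from a
parametric family chosen to match how the input was reported:

* probabilities reported as mean (95% CI)  -> Beta, moment matched with
  SE = (hi - lo) / 3.92 (symmetric normal-theory interval);
* positive costs / disutilities with an SE -> Gamma with
  shape = (mean/se)^2, scale = se^2/mean;
* compositional rows (baseline proportions, transition rows) -> Dirichlet
  parameterised directly by observed counts;
* hazard ratios -> log-normal parameterised so the *mean* of the
  distribution equals the base-case ratio.

Every fitted spec reproduces its base-case mean analytically (to 1e-6
relative), so the base case is the expectation of the PSA input draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: half-width of a 95% normal interval, both sides
_Z95_SPAN = 3.92


@dataclass
class DistributionSpec:
    """A sampling distribution attached to one model input.

    ``target`` is a dotted path naming the input the spec perturbs (used by
    the sensitivity layer); it may be empty for ad-hoc specs.
    """

    family: str  # {"beta", "gamma", "dirichlet", "lognormal", "fixed"}
    params: dict = field(default_factory=dict)
    target: str = ""

    def mean(self):
        """Analytic mean of the fitted distribution (vector for dirichlet)."""
        p = self.params
        if self.family == "fixed":
            return p["value"]
        if self.family == "beta":
            return p["alpha"] / (p["alpha"] + p["beta"])
        if self.family == "gamma":
            return p["shape"] * p["scale"]
        if self.family == "dirichlet":
            alpha = np.asarray(p["alpha"], dtype=float)
            return alpha / alpha.sum()
        if self.family == "lognormal":
            return float(np.exp(p["mu"] + 0.5 * p["sigma"] ** 2))
        raise ValueError(f"unknown family {self.family!r}")

    def sample(self, rng: np.random.Generator):
        p = self.params
        if self.family == "fixed":
            return p["value"]
        if self.family == "beta":
            return float(rng.beta(p["alpha"], p["beta"]))
        if self.family == "gamma":
            return float(rng.gamma(p["shape"], p["scale"]))
        if self.family == "dirichlet":
            return rng.dirichlet(np.asarray(p["alpha"], dtype=float))
        if self.family == "lognormal":
            return float(rng.lognormal(p["mu"], p["sigma"]))
        raise ValueError(f"unknown family {self.family!r}")


def fit_beta_from_ci(mean: float, lo: float, hi: float, target: str = "") -> DistributionSpec:
    """Moment-matched Beta from a mean and a symmetric 95% CI.

    A degenerate interval (lo == hi) yields a ``fixed`` spec.
    """
    if not (0.0 < lo <= mean <= hi < 1.0):
        raise ValueError(f"require 0 < lo <= mean <= hi < 1, got ({mean}, {lo}, {hi})")
    if lo == hi:
        return DistributionSpec("fixed", {"value": mean}, target)
    se = (hi - lo) / _Z95_SPAN
    var = se * se
    nu = mean * (1.0 - mean) / var - 1.0
    if nu <= 0.0:
        raise ValueError(f"CI too wide for Beta at mean {mean}: variance {var}")
    return DistributionSpec(
        "beta", {"alpha": mean * nu, "beta": (1.0 - mean) * nu}, target
    )


def fit_beta_from_mean_n(mean: float, n_effective: float, target: str = "") -> DistributionSpec:
    """Beta with the given mean and pseudo-sample size ``n_effective``."""
    if not 0.0 < mean < 1.0:
        return DistributionSpec("fixed", {"value": mean}, target)
    return DistributionSpec(
        "beta",
        {"alpha": mean * n_effective, "beta": (1.0 - mean) * n_effective},
        target,
    )


def fit_gamma_from_mean_se(mean: float, se: float, target: str = "") -> DistributionSpec:
    """Gamma with the given mean and standard error (shape = (mean/se)^2)."""
    if mean <= 0.0:
        raise ValueError(f"gamma mean must be positive, got {mean}")
    if se <= 0.0:
        return DistributionSpec("fixed", {"value": mean}, target)
    shape = (mean / se) ** 2
    return DistributionSpec("gamma", {"shape": shape, "scale": se * se / mean}, target)


def dirichlet_from_counts(counts, smoothing: bool = False, target: str = "") -> DistributionSpec:
    """Dirichlet parameterised by observed category counts.

    With ``smoothing`` each count gets +1, guarding against structural
    zeros; the default uses the raw counts.
    """
    alpha = np.asarray(counts, dtype=float)
    if np.any(alpha < 0):
        raise ValueError("counts must be nonnegative")
    if alpha.sum() <= 0:
        raise ValueError("at least one count must be positive")
    if smoothing:
        alpha = alpha + 1.0
    return DistributionSpec("dirichlet", {"alpha": alpha.tolist()}, target)


def lognormal_for_ratio(mean_ratio: float, sdlog: float = 0.1, target: str = "") -> DistributionSpec:
    """Log-normal whose *mean* equals ``mean_ratio`` with log-scale SD ``sdlog``."""
    if mean_ratio <= 0.0:
        raise ValueError(f"ratio must be positive, got {mean_ratio}")
    if sdlog <= 0.0:
        return DistributionSpec("fixed", {"value": mean_ratio}, target)
    mu = float(np.log(mean_ratio) - 0.5 * sdlog**2)
    return DistributionSpec("lognormal", {"mu": mu, "sigma": sdlog}, target)
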