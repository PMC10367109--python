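"""Social-pressure mixture model of the sexual-orientation continuum.

The population distribution of mean sexual orientation (MSO, on [0, 18])
is modelled as a two-component mixture of sinh-arcsinh densities:

    f(x) = (1 - pi) * f_nonss(x) + pi * f_ss(x)

where ``pi`` is the weight of the pressure-resistant same-sex (SS)
component.  A scalar social-pressure parameter ``S`` deforms both
components linearly: heteronormative pressure (S > 0) shifts and skews
the non-SS component toward the opposite-sex end of the continuum while
the SS component shifts the other way.  At S = 0 the two components
coincide in a single symmetric density centred at 9; as S grows the
mixture first skews and then, past a critical pressure, splits into a
bimodal shape with a minor mode at the SS end.

Two public objects implement this:

``PressureMixture``
    The generative model: density, CDF, sampling, quadrature moments,
    mode counting and the pressure deformation itself.
``SPTModel`` / ``SPTResults``
    A statsmodels-style estimator: built from 19-bin histogram counts of
    MSO scores, ``fit()`` maximizes the multinomial likelihood over a
    chosen free-parameter set and returns a results object with the
    estimates, log-likelihood and a ``summary()`` table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize

from .sas import SinhArcsinhParams, sas_cdf, sas_pdf, sas_sample

__all__ = [
    "Deformation",
    "PressureMixture",
    "apply_pressure",
    "count_modes",
    "critical_pressure",
    "SPTModel",
    "SPTResults",
    "BIN_EDGES",
    "BIN_CENTERS",
]

CONTINUUM = (0.0, 18.0)
CENTER = 9.0

#: Histogram convention for MSO scores: 19 unit bins centred at 0..18.
BIN_CENTERS = np.arange(19, dtype=float)
BIN_EDGES = np.arange(-0.5, 19.0, 1.0)


@dataclass(frozen=True)
class Deformation:
    """Linear response of the two components to social pressure S.

    Non-SS component:  mu1(S) = 9 - lam1*S,  eps1(S) = -kap1*S
    SS component:      mu2(S) = 9 + lam2*S,  eps2(S) = +kap2*S

    The sign pattern makes S <-> -S an exact mirror about the continuum
    centre. Defaults are chosen so that sweeping S from 0 upward
    reproduces the qualitative sequence symmetric -> skewed -> bimodal
    with the minor mode at the SS end.
    """

    lam1: float = 2.0
    kap1: float = 0.4
    lam2: float = 1.5
    kap2: float = 0.3


@dataclass(frozen=True)
class PressureMixture:
    """Two-component sinh-arcsinh mixture under social pressure S."""

    comp_nonss: SinhArcsinhParams = field(
        default_factory=lambda: SinhArcsinhParams(mu=CENTER, sigma=3.0)
    )
    comp_ss: SinhArcsinhParams = field(
        default_factory=lambda: SinhArcsinhParams(mu=CENTER, sigma=3.0)
    )
    mix_rate: float = 0.07
    pressure: float = 0.0
    deformation: Deformation = field(default_factory=Deformation)

    def __post_init__(self) -> None:
        if not (0.0 <= self.mix_rate <= 1.0):
            raise ValueError(f"mix_rate must be in [0, 1], got {self.mix_rate}")
        if not np.isfinite(self.pressure):
            raise ValueError("pressure must be finite")

    # -- density / distribution ------------------------------------------------

    def pdf(self, x):
        """Mixture density (1-pi)*f_nonss + pi*f_ss."""
        return (1.0 - self.mix_rate) * sas_pdf(x, self.comp_nonss) + (
            self.mix_rate
        ) * sas_pdf(x, self.comp_ss)

    def cdf(self, x):
        return (1.0 - self.mix_rate) * sas_cdf(x, self.comp_nonss) + (
            self.mix_rate
        ) * sas_cdf(x, self.comp_ss)

    def sample(self, n: int, seed=None):
        """Draw n variates; component membership then conditional draw."""
        rng = np.random.default_rng(seed)
        is_ss = rng.random(n) < self.mix_rate
        out = sas_sample(n, self.comp_nonss, rng)
        n_ss = int(is_ss.sum())
        if n_ss:
            out[is_ss] = sas_sample(n_ss, self.comp_ss, rng)
        return out

    # -- pressure deformation --------------------------------------------------

    def at_pressure(self, S: float) -> "PressureMixture":
        """Return the mixture deformed to pressure S (see :func:`apply_pressure`)."""
        return apply_pressure(self, S)

    # -- diagnostics -----------------------------------------------------------

    def moments(self):
        """(mean, sd, skewness, kurtosis) by adaptive quadrature.

        Kurtosis is non-excess (3 for a Gaussian). Integration runs over
        a generous envelope of both components rather than the bare
        continuum so that normalization is preserved.
        """
        lo, hi = self._envelope()
        opts = dict(limit=200, epsabs=1e-10, epsrel=1e-10)

        total, _ = integrate.quad(self.pdf, lo, hi, **opts)
        if not np.isclose(total, 1.0, atol=1e-6):
            raise RuntimeError(f"density quadrature failed to normalize: {total}")
        mean, _ = integrate.quad(lambda x: x * self.pdf(x), lo, hi, **opts)
        var, _ = integrate.quad(
            lambda x: (x - mean) ** 2 * self.pdf(x), lo, hi, **opts
        )
        sd = np.sqrt(var)
        m3, _ = integrate.quad(
            lambda x: (x - mean) ** 3 * self.pdf(x), lo, hi, **opts
        )
        m4, _ = integrate.quad(
            lambda x: (x - mean) ** 4 * self.pdf(x), lo, hi, **opts
        )
        return mean, sd, m3 / sd**3, m4 / var**2

    def _envelope(self):
        # extreme component quantiles, so heavy tails (delta < 1) are covered
        from .sas import sas_ppf

        q = np.array([1e-13, 1.0 - 1e-13])
        lo1, hi1 = sas_ppf(q, self.comp_nonss)
        lo2, hi2 = sas_ppf(q, self.comp_ss)
        return min(lo1, lo2), max(hi1, hi2)

    def bin_probabilities(self, edges=BIN_EDGES):
        """Bin probabilities from CDF differences, tails folded into end bins."""
        cdf = self.cdf(np.asarray(edges, dtype=float))
        p = np.diff(cdf)
        p[0] += cdf[0]
        p[-1] += 1.0 - cdf[-1]
        return p

    def to_dict(self) -> dict:
        return {
            "comp_nonss": vars(self.comp_nonss) | {},
            "comp_ss": vars(self.comp_ss) | {},
            "mix_rate": self.mix_rate,
            "pressure": self.pressure,
            "deformation": vars(self.deformation) | {},
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "PressureMixture":
        return cls(
            comp_nonss=SinhArcsinhParams(**d["comp_nonss"]),
            comp_ss=SinhArcsinhParams(**d["comp_ss"]),
            mix_rate=d["mix_rate"],
            pressure=d.get("pressure", 0.0),
            deformation=Deformation(**d.get("deformation", {})),
        )


def apply_pressure(model: PressureMixture, S: float) -> PressureMixture:
    """Deform a base (S = 0) mixture to social pressure S.

    The non-SS component moves toward the opposite-sex end
    (mu1 = 9 - lam1*S, eps1 = -kap1*S) and the SS component toward the
    same-sex end (mu2 = 9 + lam2*S, eps2 = +kap2*S); sigma, delta and the
    mixture rate are untouched. Negative S mirrors the deformation.
    Component locations pushed outside [0, 18] are clipped with a warning.
    """
    if not np.isfinite(S):
        raise ValueError("pressure S must be finite")
    d = model.deformation
    mu1 = CENTER - d.lam1 * S
    mu2 = CENTER + d.lam2 * S
    lo, hi = CONTINUUM
    if not (lo <= mu1 <= hi) or not (lo <= mu2 <= hi):
        warnings.warn(
            f"pressure S={S} pushes a component location outside {CONTINUUM}; clipping",
            RuntimeWarning,
            stacklevel=2,
        )
        mu1 = float(np.clip(mu1, lo, hi))
        mu2 = float(np.clip(mu2, lo, hi))
    return PressureMixture(
        comp_nonss=model.comp_nonss.replace(mu=mu1, epsilon=-d.kap1 * S),
        comp_ss=model.comp_ss.replace(mu=mu2, epsilon=d.kap2 * S),
        mix_rate=model.mix_rate,
        pressure=S,
        deformation=d,
    )


def count_modes(model: PressureMixture, grid_step: float = 0.01) -> int:
    """Count modes of the mixture density on a regular grid over [0, 18].

    A mode is a strict local maximum after collapsing plateaus of equal
    density values; maxima at either endpoint of the continuum count.
    """
    if not (0 < grid_step <= 0.01):
        raise ValueError("grid_step must be in (0, 0.01]")
    lo, hi = CONTINUUM
    x = np.arange(lo, hi + grid_step / 2, grid_step)
    if x.size < 3:
        raise ValueError("degenerate grid")
    y = model.pdf(x)
    # collapse plateaus: keep one representative per run of equal values
    keep = np.empty(y.size, dtype=bool)
    keep[0] = True
    keep[1:] = y[1:] != y[:-1]
    yc = y[keep]
    if yc.size == 1:
        return 1
    modes = 0
    for i in range(yc.size):
        left_ok = i == 0 or yc[i] > yc[i - 1]
        right_ok = i == yc.size - 1 or yc[i] > yc[i + 1]
        if left_ok and right_ok:
            modes += 1
    return modes


def critical_pressure(
    model: PressureMixture,
    S_range: tuple[float, float],
    tol: float = 1e-3,
    grid_step: float = 0.01,
):
    """Smallest pressure (within ``tol``) at which the density turns bimodal.

    Bisects on S between the endpoints of ``S_range``, which must differ
    in mode count. Returns None when no unimodal/bimodal transition
    exists on the interval (e.g. a deformation with no effect).
    """
    s_lo, s_hi = S_range
    n_lo = count_modes(model.at_pressure(s_lo), grid_step)
    n_hi = count_modes(model.at_pressure(s_hi), grid_step)
    if n_lo == n_hi:
        return None
    while s_hi - s_lo > tol:
        mid = 0.5 * (s_lo + s_hi)
        if count_modes(model.at_pressure(mid), grid_step) >= 2:
            s_hi = mid
        else:
            s_lo = mid
    return s_hi


# ---------------------------------------------------------------------------
# Binned maximum-likelihood estimation
# ---------------------------------------------------------------------------

_PARAM_ORDER = (
    "mu1", "sigma1", "eps1", "delta1",
    "mu2", "sigma2", "eps2", "delta2",
    "mix_rate",
)

_BOUNDS = {
    "mu1": (0.0, 18.0),
    "mu2": (0.0, 18.0),
    "sigma1": (0.1, 20.0),
    "sigma2": (0.1, 20.0),
    "eps1": (-5.0, 5.0),
    "eps2": (-5.0, 5.0),
    "delta1": (0.1, 20.0),
    "delta2": (0.1, 20.0),
    "mix_rate": (0.001, 0.5),
}


def _mixture_from_params(p: dict) -> PressureMixture:
    return PressureMixture(
        comp_nonss=SinhArcsinhParams(p["mu1"], p["sigma1"], p["eps1"], p["delta1"]),
        comp_ss=SinhArcsinhParams(p["mu2"], p["sigma2"], p["eps2"], p["delta2"]),
        mix_rate=p["mix_rate"],
    )


class SPTModel:
    """Binned maximum-likelihood estimator for the pressure mixture.

    Built from 19 histogram counts of MSO scores over unit bins centred
    at 0..18; ``fit`` maximizes the multinomial log-likelihood with bin
    probabilities taken from CDF differences at the bin edges (tails
    folded into the end bins).

    Parameters
    ----------
    bin_counts : array-like of 19 non-negative ints
        Observed MSO histogram; total must be at least 100.
    free : sequence of str, optional
        Names of parameters to estimate, from
        mu1, sigma1, eps1, delta1, mu2, sigma2, eps2, delta2, mix_rate.
        The remainder stay fixed at their start values. Default frees
        mu1, sigma1, eps1 and mix_rate.
    start : mapping, optional
        Start values (also the fixed values for non-free parameters).
    """

    DEFAULT_FREE = ("mu1", "sigma1", "eps1", "mix_rate")

    def __init__(self, bin_counts, free=None, start=None):
        counts = np.asarray(bin_counts, dtype=float)
        if counts.shape != (19,):
            raise ValueError("bin_counts must have exactly 19 entries")
        if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
            raise ValueError("bin_counts must be non-negative integers")
        if counts.sum() < 100:
            raise ValueError("need a total count of at least 100 to fit")
        self.counts = counts
        self.nobs = int(counts.sum())
        self.free = tuple(free) if free is not None else self.DEFAULT_FREE
        unknown = set(self.free) - set(_PARAM_ORDER)
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")

        defaults = {
            "mu1": 9.0, "sigma1": 3.0, "eps1": 0.0, "delta1": 1.0,
            "mu2": 9.0, "sigma2": 3.0, "eps2": 0.0, "delta2": 1.0,
            "mix_rate": 0.07,
        }
        if start:
            defaults.update(start)
        self.start = defaults

    @classmethod
    def from_scores(cls, scores, **kwargs) -> "SPTModel":
        """Bin raw MSO scores on [0, 18] into the 19-bin convention."""
        scores = np.asarray(scores, dtype=float)
        if np.any((scores < 0) | (scores > 18)):
            raise ValueError("scores must lie in [0, 18]")
        counts, _ = np.histogram(scores, bins=BIN_EDGES)
        return cls(counts, **kwargs)

    def loglike(self, params: dict) -> float:
        """Multinomial log-likelihood (without the constant term)."""
        p = self.start | dict(params)
        probs = _mixture_from_params(p).bin_probabilities()
        probs = np.clip(probs, 1e-300, None)
        return float(self.counts @ np.log(probs))

    def fit(self, xtol: float = 1e-8, maxiter: int = 20000) -> "SPTResults":
        """Maximize the binned likelihood with bounded Nelder-Mead."""
        if np.count_nonzero(self.counts) <= 1:
            # all mass in one bin: no identifiable shape
            return SPTResults(self, dict(self.start), -np.inf, converged=False)

        x0 = np.array([self.start[k] for k in self.free])
        bounds = [_BOUNDS[k] for k in self.free]

        def neg_ll(x):
            return -self.loglike(dict(zip(self.free, x)))

        res = optimize.minimize(
            neg_ll,
            x0,
            method="Nelder-Mead",
            bounds=bounds,
            options={
                "xatol": xtol,
                "fatol": xtol,
                "maxiter": maxiter,
                "maxfev": maxiter,
            },
        )
        params = self.start | dict(zip(self.free, res.x))
        return SPTResults(self, params, -res.fun, converged=bool(res.success))


class SPTResults:
    """Container for a fitted :class:`SPTModel`.

    Attributes
    ----------
    params : dict
        Full parameter set (free estimates merged over fixed values).
    llf : float
        Maximized multinomial log-likelihood.
    converged : bool
        Optimizer success flag; on failure the best point found is kept.
    """

    def __init__(self, model: SPTModel, params: dict, llf: float, converged: bool):
        self.model = model
        self.params = params
        self.llf = llf
        self.converged = converged

    @property
    def mixture(self) -> PressureMixture:
        """The fitted generative mixture."""
        return _mixture_from_params(self.params)

    def expected_counts(self):
        return self.model.nobs * self.mixture.bin_probabilities()

    def summary(self) -> str:
        lines = [
            "Social-pressure mixture: binned ML fit",
            "=" * 46,
            f"{'observations':<24}{self.model.nobs:>22}",
            f"{'log-likelihood':<24}{self.llf:>22.3f}",
            f"{'converged':<24}{str(self.converged):>22}",
            "-" * 46,
            f"{'parameter':<12}{'estimate':>16}{'free':>16}",
            "-" * 46,
        ]
        for name in _PARAM_ORDER:
            tag = "yes" if name in self.model.free else "fixed"
            lines.append(f"{name:<12}{self.params[name]:>16.4f}{tag:>16}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": {k: float(v) for k, v in self.params.items()},
            "free": list(self.model.free),
            "llf": float(self.llf),
            "converged": self.converged,
            "nobs": self.model.nobs,
        }
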