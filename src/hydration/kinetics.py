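"""Biosensor kinetics fitting and mutant affinity energetics.

Association traces at several analyte concentrations follow the single-
exponential pseudo-first-order model

    A(t) = A_inf (1 - exp(-k_obs t)),     k_obs = k_on C + k_off,

and dissociation follows D(t) = D_0 exp(-k_off t).  The fit proceeds as
per-trace exponential fits followed by a weighted linear regression of k_obs
on concentration (slope = k_on); k_off is taken from the dissociation decay
and K_D = k_off / k_on.  Mutant-vs-wild-type affinity losses are expressed as
a fold change and a binding free-energy difference ΔΔG = RT ln(K_D,mut /
K_D,wt).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

#: Gas constant in kcal mol⁻¹ K⁻¹.
R_KCAL = 1.9872e-3

ASSOCIATION = "association"
DISSOCIATION = "dissociation"


class FitError(RuntimeError):
    """Raised when a kinetic fit fails to converge."""


@dataclass
class KineticsDataset:
    """Traces of (time s, normalized response) per analyte concentration (M)."""

    traces: list[tuple[float, np.ndarray, np.ndarray]]
    phase: str = ASSOCIATION

    def __post_init__(self) -> None:
        if self.phase not in (ASSOCIATION, DISSOCIATION):
            raise ValueError(f"unknown phase {self.phase!r}")
        for conc, t, y in self.traces:
            if conc <= 0:
                raise ValueError("analyte concentrations must be positive")
            t = np.asarray(t, dtype=float)
            if np.any(np.diff(t) <= 0):
                raise ValueError("times must be strictly increasing")


@dataclass
class RateFit:
    kon: float
    koff: float
    se_kon: float = float("nan")
    se_koff: float = float("nan")
    valid: bool = True
    diagnostics: dict = field(default_factory=dict)

    @property
    def kd(self) -> float:
        return self.koff / self.kon


@dataclass
class AffinityComparison:
    kd_wt: float
    kd_mut: float
    temperature: float

    @property
    def factor(self) -> float:
        return self.kd_mut / self.kd_wt

    @property
    def ddg(self) -> float:
        """Binding free-energy penalty, kcal/mol (positive = mutant weaker)."""
        return R_KCAL * self.temperature * np.log(self.factor)


def _fit_single_exponential(t: np.ndarray, y: np.ndarray, rising: bool
                            ) -> tuple[float, float]:
    """Fit one trace; returns (rate, rate standard error)."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    amp0 = y.max() if rising else max(y[0], 1e-12)
    # seed the rate from the half-rise / half-decay time
    target = amp0 * 0.5
    idx = np.argmin(np.abs(y - target))
    t_half = t[idx] if t[idx] > 0 else (t[1] if len(t) > 1 else 1.0)
    k0 = np.log(2.0) / t_half

    if rising:
        def f(tt, amp, k):
            return amp * (1.0 - np.exp(-k * tt))
    else:
        def f(tt, amp, k):
            return amp * np.exp(-k * tt)
    try:
        popt, pcov = optimize.curve_fit(f, t, y, p0=[amp0, k0], maxfev=10000)
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitError(f"exponential fit did not converge: {exc}") from exc
    k = float(popt[1])
    se = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else float("nan")
    return k, se


def fit_kinetics(assoc: KineticsDataset, dissoc: KineticsDataset) -> RateFit:
    """Global single-exponential analysis of association + dissociation data.

    Requires at least two association concentrations.  Rates fitted negative
    are reported with ``valid=False``; diagnostics carry the per-trace
    observed rates and the k_obs regression.
    """
    if assoc.phase != ASSOCIATION or dissoc.phase != DISSOCIATION:
        raise ValueError("datasets must be one association and one dissociation")
    if len(assoc.traces) < 2:
        raise ValueError("need at least 2 association concentrations to "
                         "separate kon from koff")

    concs, kobs, kobs_se = [], [], []
    for conc, t, y in assoc.traces:
        k, se = _fit_single_exponential(t, y, rising=True)
        concs.append(conc)
        kobs.append(k)
        kobs_se.append(se)
    concs = np.array(concs)
    kobs = np.array(kobs)
    w = np.array([1.0 / se**2 if np.isfinite(se) and se > 0 else 1.0
                  for se in kobs_se])

    # weighted linear regression k_obs = kon * C + intercept
    W = np.diag(w)
    Xd = np.column_stack([concs, np.ones_like(concs)])
    beta, *_ = np.linalg.lstsq(np.sqrt(W) @ Xd, np.sqrt(w) * kobs, rcond=None)
    kon = float(beta[0])
    resid = kobs - Xd @ beta
    dof = max(len(concs) - 2, 1)
    s2 = float(resid @ (w * resid)) / dof
    cov = s2 * np.linalg.inv(Xd.T @ W @ Xd)
    se_kon = float(np.sqrt(cov[0, 0]))

    koff_vals, koff_ses = [], []
    for _conc, t, y in dissoc.traces:
        k, se = _fit_single_exponential(t, y, rising=False)
        koff_vals.append(k)
        koff_ses.append(se)
    koff = float(np.mean(koff_vals))
    se_koff = float(np.sqrt(np.sum(np.square(koff_ses))) / len(koff_ses))

    valid = kon > 0 and koff > 0
    return RateFit(kon=kon, koff=koff, se_kon=se_kon, se_koff=se_koff,
                   valid=valid,
                   diagnostics={"concentrations_M": concs.tolist(),
                                "k_obs_s": kobs.tolist(),
                                "k_obs_intercept_s": float(beta[1]),
                                "koff_per_trace_s": koff_vals})


def kd_from_rates(kon: float, koff: float) -> float:
    """Equilibrium dissociation constant K_D = k_off / k_on (M)."""
    if kon <= 0 or koff <= 0:
        raise ValueError("kon and koff must be positive")
    return koff / kon


def compare_affinities(kd_wt: float, kd_mut: float,
                       temperature: float = 298.15) -> AffinityComparison:
    """Fold affinity change and ΔΔG between wild type and mutant.

    ΔΔG = RT ln(K_D,mut / K_D,wt) in kcal/mol, positive when the mutant binds
    more weakly.
    """
    if kd_wt <= 0 or kd_mut <= 0:
        raise ValueError("dissociation constants must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    return AffinityComparison(kd_wt=kd_wt, kd_mut=kd_mut, temperature=temperature)
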