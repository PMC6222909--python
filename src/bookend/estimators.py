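"""Free-energy estimators between Hamiltonian levels.

Three named estimators over per-frame potential-energy differences:

* ``exp_zwanzig`` -- one-sided exponential (free energy perturbation),
  dG = -(1/beta) ln < exp(-beta dU) > over samples from the reference state;
* ``bar`` -- Bennett's acceptance ratio, the minimum-variance two-sided
  estimator, solved self-consistently by bracketed root finding;
* ``nbb`` -- Non-Boltzmann Bennett, the BAR generalization in which samples
  drawn from biased sampling states are reweighted toward the intended
  target states by their bias energies b = U_sampling - U_target.

All exponential averages go through log-sum-exp with max-subtraction:
poor phase-space overlap (large |beta dU|) is precisely the regime this
machinery exists for.  Uncertainties within a single sample set are not
reported; the protocol-level uncertainty comes from independent repeats
(see :func:`aggregate`), matching the four-repeat convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logsumexp

__all__ = [
    "WorkSampleSet",
    "WindowResult",
    "FreeEnergyResult",
    "EstimatorError",
    "exp_zwanzig",
    "bar",
    "nbb",
    "overlap_diagnostics",
    "aggregate",
]


class EstimatorError(RuntimeError):
    """An estimator could not produce a defensible answer."""


@dataclass
class WorkSampleSet:
    """Forward/reverse potential-energy differences between states A and B.

    ``forward`` holds dU_f = U_B(x) - U_A(x) on frames from (possibly
    biased) sampling of A; ``reverse`` holds dU_r = U_A(x) - U_B(x) on
    frames from B (may be absent for one-sided estimation).  ``bias_*``
    are per-frame bias energies b = U_sampling - U_target for each side,
    zero/None when the sampling state is the target state.  ``beta`` is
    1/(k_B T) in mol/kcal.
    """

    forward: np.ndarray
    reverse: np.ndarray | None = None
    bias_forward: np.ndarray | None = None
    bias_reverse: np.ndarray | None = None
    beta: float = 1.0

    def __post_init__(self) -> None:
        self.forward = np.asarray(self.forward, dtype=float)
        if self.forward.size == 0:
            raise EstimatorError("forward samples must be non-empty")
        if self.reverse is not None:
            self.reverse = np.asarray(self.reverse, dtype=float)
        if self.beta <= 0:
            raise EstimatorError("beta must be positive")
        for name in ("bias_forward", "bias_reverse"):
            b = getattr(self, name)
            if b is not None:
                b = np.asarray(b, dtype=float)
                setattr(self, name, b)
        if self.bias_forward is not None and self.bias_forward.shape != self.forward.shape:
            raise EstimatorError("bias_forward length must match forward samples")
        if self.bias_reverse is not None:
            if self.reverse is None or self.bias_reverse.shape != self.reverse.shape:
                raise EstimatorError("bias_reverse length must match reverse samples")
        arrays = [self.forward, self.reverse, self.bias_forward, self.bias_reverse]
        for a in arrays:
            if a is not None and not np.all(np.isfinite(a)):
                raise EstimatorError("work samples and biases must be finite")

    def swapped(self) -> "WorkSampleSet":
        """The same data with the roles of A and B exchanged."""
        if self.reverse is None:
            raise EstimatorError("cannot swap a one-sided sample set")
        return WorkSampleSet(
            self.reverse, self.forward, self.bias_reverse, self.bias_forward, self.beta
        )


@dataclass
class WindowResult:
    window: str
    delta_g: float
    diagnostics: dict = field(default_factory=dict)


@dataclass
class FreeEnergyResult:
    """A free-energy difference with repeat statistics and provenance.

    ``delta_g`` is the total (kcal/mol); ``std_dev`` the sample SD across
    repeats (0 for a single estimate); ``per_window`` the additive window
    breakdown, which must sum to the total.
    """

    delta_g: float
    std_dev: float = 0.0
    per_window: list[WindowResult] = field(default_factory=list)
    method: str = "EXP"
    n_repeats: int = 1
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.std_dev < 0:
            raise EstimatorError("std_dev must be >= 0")
        if self.per_window:
            s = sum(w.delta_g for w in self.per_window)
            if abs(s - self.delta_g) > 1e-9:
                raise EstimatorError(
                    f"per-window sum {s} does not match total {self.delta_g}"
                )

    def to_dict(self) -> dict:
        return {
            "delta_g": self.delta_g,
            "std_dev": self.std_dev,
            "method": self.method,
            "n_repeats": self.n_repeats,
            "per_window": [
                {"window": w.window, "delta_g": w.delta_g, "diagnostics": w.diagnostics}
                for w in self.per_window
            ],
            "provenance": self.provenance,
        }


def _ess(log_w: np.ndarray) -> float:
    """Effective sample size (sum w)^2 / sum w^2 from log-weights."""
    lw = log_w - log_w.max()
    w = np.exp(lw)
    return float(w.sum() ** 2 / np.sum(w ** 2))


def exp_zwanzig(samples: WorkSampleSet) -> FreeEnergyResult:
    """One-sided exponential estimator dG = -(1/beta) ln<exp(-beta dU_f)>."""
    beta = samples.beta
    work = samples.forward
    log_w = -beta * work
    if samples.bias_forward is not None:
        # biased sampling: reweight each frame by exp(+beta b)
        log_bias = beta * samples.bias_forward
        dg = -(logsumexp(log_w + log_bias) - logsumexp(log_bias)) / beta
        ess = _ess(log_w + log_bias)
    else:
        dg = -(logsumexp(log_w) - np.log(work.size)) / beta
        ess = _ess(log_w)
    return FreeEnergyResult(
        float(dg),
        per_window=[WindowResult("0", float(dg), {"ess_forward": ess, "n_forward": work.size})],
        method="EXP",
    )


def _log_weights(bias: np.ndarray | None, n: int, beta: float) -> np.ndarray:
    if bias is None:
        return np.zeros(n)
    return beta * bias


def _normalized_weights(log_w: np.ndarray) -> np.ndarray:
    """Weights scaled to sum to the sample count (all 1.0 when uniform)."""
    w = np.exp(log_w - log_w.max())
    return w * (log_w.size / w.sum())


def _solve_bennett(
    duf: np.ndarray,
    dur: np.ndarray,
    wf: np.ndarray,
    wr: np.ndarray,
    beta: float,
    tol: float,
    max_iter: int,
) -> float:
    """Root of the (weighted) self-consistent Bennett equation.

    With M = ln(n_f/n_r), find C such that
    sum_f W_f / (1 + exp(beta(dU_f - C) + M))
      = sum_r W_r / (1 + exp(beta(dU_r + C) - M));
    dG = C.  The left side is increasing and the right side decreasing in
    C, so the difference is monotone and bisection-style bracketing is
    guaranteed to converge.
    """
    m = np.log(duf.size / dur.size)

    def g(c: float) -> float:
        lhs = np.sum(wf * expit(-(beta * (duf - c) + m)))
        rhs = np.sum(wr * expit(-(beta * (dur + c) - m)))
        return lhs - rhs

    # bracket around the two one-sided exponential estimates
    lw_f = -beta * duf + np.log(wf)
    lw_r = -beta * dur + np.log(wr)
    exp_f = -(logsumexp(lw_f) - np.log(wf.sum())) / beta
    exp_r = (logsumexp(lw_r) - np.log(wr.sum())) / beta  # = -EXP(B->A)
    lo = min(exp_f, exp_r) - 50.0
    hi = max(exp_f, exp_r) + 50.0
    for _ in range(max_iter):
        if g(lo) < 0.0 < g(hi):
            break
        span = hi - lo
        lo -= span
        hi += span
    else:
        raise EstimatorError(
            "Bennett solve failed to bracket a root; overlap diagnostics: "
            f"ESS_f={_ess(lw_f):.2f}, ESS_r={_ess(lw_r):.2f}, "
            f"EXP_f={exp_f:.3f}, -EXP_r={exp_r:.3f}"
        )
    return float(brentq(g, lo, hi, xtol=tol, maxiter=200))


def nbb(samples: WorkSampleSet, tol: float = 1e-8, max_iter: int = 20) -> FreeEnergyResult:
    """Non-Boltzmann Bennett estimator.

    Each sample i carries a normalized weight proportional to
    exp(+beta b_i) for its side, undoing the sampling bias; with all biases
    zero this reduces exactly (bit-for-bit) to :func:`bar`.
    """
    if samples.reverse is None:
        raise EstimatorError("NBB requires samples in both directions")
    beta = samples.beta
    lwf = _log_weights(samples.bias_forward, samples.forward.size, beta)
    lwr = _log_weights(samples.bias_reverse, samples.reverse.size, beta)
    ess_f, ess_r = _ess(lwf), _ess(lwr)
    if min(ess_f, ess_r) < 2.0:
        raise EstimatorError(
            f"bias weights are numerically degenerate (ESS_f={ess_f:.2f}, "
            f"ESS_r={ess_r:.2f}); the biased states overlap too little with their targets"
        )
    wf = _normalized_weights(lwf)
    wr = _normalized_weights(lwr)
    dg = _solve_bennett(samples.forward, samples.reverse, wf, wr, beta, tol, max_iter)
    method = "BAR" if samples.bias_forward is None and samples.bias_reverse is None else "NBB"
    diag = {
        "ess_forward": _ess(-beta * samples.forward + lwf),
        "ess_reverse": _ess(-beta * samples.reverse + lwr),
        "bias_ess_forward": ess_f,
        "bias_ess_reverse": ess_r,
        "n_forward": samples.forward.size,
        "n_reverse": samples.reverse.size,
    }
    return FreeEnergyResult(dg, per_window=[WindowResult("0", dg, diag)], method=method)


def bar(samples: WorkSampleSet, tol: float = 1e-8, max_iter: int = 20) -> FreeEnergyResult:
    """Bennett's acceptance ratio estimate from two-sided work samples.

    Ignores any biases on the sample set (use :func:`nbb` for those).
    """
    if samples.reverse is None:
        raise EstimatorError("BAR requires samples in both directions")
    unbiased = WorkSampleSet(samples.forward, samples.reverse, beta=samples.beta)
    out = nbb(unbiased, tol=tol, max_iter=max_iter)
    out.method = "BAR"
    return out


def bar_asymptotic_variance(samples: WorkSampleSet, delta_g: float) -> float:
    """Bennett's large-sample variance of a BAR estimate (a diagnostic;
    protocol-level uncertainties still come from independent repeats).

    With Fermi terms f evaluated at the solution C = delta_g,
    var = (1/beta^2) [ (<f_F^2>/<f_F>^2 - 1)/n_f + (<f_R^2>/<f_R>^2 - 1)/n_r ].
    """
    if samples.reverse is None:
        raise EstimatorError("asymptotic variance needs both directions")
    beta = samples.beta
    m = np.log(samples.forward.size / samples.reverse.size)
    ff = expit(-(beta * (samples.forward - delta_g) + m))
    fr = expit(-(beta * (samples.reverse + delta_g) - m))
    term_f = (np.mean(ff ** 2) / np.mean(ff) ** 2 - 1.0) / ff.size
    term_r = (np.mean(fr ** 2) / np.mean(fr) ** 2 - 1.0) / fr.size
    return float((term_f + term_r) / beta ** 2)


def overlap_diagnostics(samples: WorkSampleSet) -> dict:
    """Phase-space-overlap diagnostics.

    ``ess_forward``/``ess_reverse`` are effective sample sizes of the
    exponential reweighting factors; ``exp_gap`` is the spread between the
    two one-sided exponential estimates (EXP_forward minus -EXP_reverse),
    zero in the perfect-overlap limit.
    """
    beta = samples.beta
    out = {"ess_forward": _ess(-beta * samples.forward), "ess_reverse": None, "exp_gap": None}
    if samples.reverse is not None and samples.reverse.size:
        out["ess_reverse"] = _ess(-beta * samples.reverse)
        exp_f = exp_zwanzig(WorkSampleSet(samples.forward, beta=beta)).delta_g
        exp_r = exp_zwanzig(WorkSampleSet(samples.reverse, beta=beta)).delta_g
        out["exp_gap"] = exp_f - (-exp_r)
    return out


def aggregate(results: Sequence[Sequence[FreeEnergyResult]]) -> FreeEnergyResult:
    """Combine per-window results across independent repeats.

    ``results[r][w]`` is window w of repeat r.  The repeat total is the sum
    over its windows; the report is mean +/- sample SD (n-1 denominator)
    over repeats, with a per-window mean breakdown.
    """
    if not results or not results[0]:
        raise EstimatorError("aggregate needs at least one repeat with one window")
    n_windows = len(results[0])
    methods = {r.method for rep in results for r in rep}
    for rep in results:
        if len(rep) != n_windows:
            raise EstimatorError("mismatched window structure across repeats")
    totals = np.array([sum(r.delta_g for r in rep) for rep in results])
    mean = float(totals.mean())
    sd = float(totals.std(ddof=1)) if len(totals) > 1 else 0.0
    per_window = []
    for w in range(n_windows):
        vals = np.array([rep[w].delta_g for rep in results])
        per_window.append(
            WindowResult(
                results[0][w].per_window[0].window if results[0][w].per_window else str(w),
                float(vals.mean()),
                {"repeat_values": vals.tolist()},
            )
        )
    total = sum(w.delta_g for w in per_window)
    # guard against floating-point drift between mean-of-sums and sum-of-means
    if abs(total - mean) > 1e-9:
        mean = total
    return FreeEnergyResult(
        mean,
        std_dev=sd,
        per_window=per_window,
        method="+".join(sorted(methods)),
        n_repeats=len(results),
        provenance={"repeat_totals": totals.tolist()},
    )
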