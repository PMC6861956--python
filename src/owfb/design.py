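"""Design of spectral-localization-optimal orthogonal wavelet filter banks.

A two-channel orthogonal wavelet filter bank is fully determined by its
analysis low-pass FIR filter ``a0`` (length ``N``, even).  The design
criterion used here is the mean squared spectral localization (MSSL)

    sigma_f^2 = (1 / (2 pi E)) * integral_{-pi}^{pi} f^2 |A0(e^{jf})|^2 df,

the second moment of the filter's energy spectrum about DC, where ``E`` is
the filter energy.  Minimizing sigma_f^2 concentrates the low-pass response
near zero frequency, which simultaneously controls pass-band ripple and
roll-off without requiring band-edge frequencies to be chosen a priori.

The problem is non-convex in ``a0`` but becomes convex in the *product
filter* ``P(z) = A0(z) B0(z)`` with ``b0`` the time reverse of ``a0``, so
that ``P(e^{jf}) = |A0(e^{jf})|^2 >= 0``.  With the one-sided
autocorrelation sequence ``p(0..N-1)`` as the decision variable, the
orthogonality (perfect-reconstruction) condition is the linear half-band
constraint ``p(0)=1, p(2m)=0``; a zero-moment (regularity) order of ``M``
-- ``2M`` zeros of ``P`` at ``z = -1`` -- is a family of ``M`` further
linear constraints; and the MSSL is the linear functional ``s . p`` with

    s = [pi^2/3, -4/1^2, 0, -4/3^2, 0, ...]        (see objective_vector).

The only non-trivial constraint is the semi-infinite spectral nonnegativity
``P(e^{jf}) >= 0`` on ``[0, pi]``; exactly the constraint that the KYP
(trace) parameterization turns into a finite positive-semidefinite
condition.  This module solves the identical convex program with a
deterministic cutting-plane linear-programming scheme (constraint exchange
on the frequency axis) followed by a Newton/least-squares polish that
places the optimum's double spectral zeros exactly, and then certifies the
result with the rank-one PSD matrix ``Z = a0 a0^T``, which satisfies the
trace parameterization ``p(m) = sum_n Z[n, n+m]`` by construction.

The optimal ``a0`` is finally recovered from ``p`` by minimum-phase
spectral factorization, and the remaining three filters follow from
quadrature conjugation:

    a1(n) = (-1)^n     a0(N-1-n)      (analysis high-pass)
    b0(n) =            a0(N-1-n)      (synthesis low-pass, time reverse)
    b1(n) = (-1)^(n+1) a0(n)          (synthesis high-pass)

With these conventions the two-channel perfect-reconstruction identities
hold with zero amplitude distortion and a pure delay of ``N-1`` samples.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import least_squares, linprog, minimize, minimize_scalar

__all__ = [
    "DesignSpec",
    "ProductFilter",
    "WaveletFilterBank",
    "SDPCertificate",
    "VerificationReport",
    "InfeasibleDesignError",
    "FactorizationError",
    "objective_vector",
    "design_product_filter",
    "evaluate_product_spectrum",
    "spectral_factorize",
    "design_filter_bank",
    "verify_filterbank",
    "save_bank",
    "load_bank",
]


class InfeasibleDesignError(ValueError):
    """Raised when the requested (N, M) admits no orthogonal filter bank."""


class FactorizationError(RuntimeError):
    """Raised when a product filter cannot be spectrally factorized."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignSpec:
    """Knobs of the filter-bank design problem.

    Parameters
    ----------
    filter_length : int
        Number of taps ``N`` of the analysis low-pass filter; must be even.
    zero_moments : int
        Regularity order ``M``; the product filter carries ``2M`` zeros at
        ``z = -1``.  ``1 <= M <= N/2``; ``M = N/2`` exhausts every degree of
        freedom and forces the maximal-regularity (Daubechies) solution.
    psd_epsilon : float
        Numerical floor used to absorb solver noise in the spectral
        nonnegativity constraint before factorization.
    solver_tolerance : float
        Accuracy target of the optimizer; also the slack allowed when the
        returned solution is checked against its constraints.
    """

    filter_length: int
    zero_moments: int
    psd_epsilon: float = 1e-10
    solver_tolerance: float = 1e-9

    def __post_init__(self) -> None:
        N, M = self.filter_length, self.zero_moments
        if N < 2 or N % 2:
            raise InfeasibleDesignError(
                f"filter_length must be an even integer >= 2, got {N}"
            )
        if M < 1:
            raise InfeasibleDesignError(f"zero_moments must be >= 1, got {M}")
        if M > N // 2:
            raise InfeasibleDesignError(
                f"regularity constraints infeasible: zero_moments={M} exceeds "
                f"filter_length/2={N // 2}; the half-band and zero-moment "
                "constraint families admit no common product filter"
            )
        if self.psd_epsilon < 0:
            raise ValueError("psd_epsilon must be nonnegative")
        if self.solver_tolerance <= 0:
            raise ValueError("solver_tolerance must be positive")


@dataclass(frozen=True)
class ProductFilter:
    """One-sided autocorrelation sequence ``p(0..N-1)`` of ``P(z)``.

    ``P(z)`` is symmetric with full support ``-(N-1)..(N-1)`` and
    ``p(-m) = p(m)``; only the one-sided half is stored.
    ``touch_frequencies`` records the interior frequencies (if known from
    the optimizer) where the spectrum touches zero; they let the spectral
    factorizer deflate those double zeros exactly.
    """

    p: np.ndarray
    touch_frequencies: tuple[float, ...] = ()
    N: int = field(init=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "N", len(p))
        object.__setattr__(
            self, "touch_frequencies", tuple(self.touch_frequencies)
        )

    def validate(self, tolerance: float = 1e-8) -> None:
        """Check the half-band structure and spectral nonnegativity."""
        p = self.p
        if abs(p[0] - 1.0) > tolerance:
            raise ValueError(f"half-band violated: p(0) = {p[0]!r} != 1")
        even = p[2::2]
        if even.size and np.abs(even).max() > tolerance:
            raise ValueError("half-band violated: p(2m) != 0 for some m >= 1")
        f = np.linspace(0.0, np.pi, 4097)
        spec = evaluate_product_spectrum(self, f)
        if spec.min() < -tolerance:
            raise ValueError(
                f"product spectrum dips to {spec.min():.3e} below zero"
            )

    def full(self) -> np.ndarray:
        """Two-sided coefficient sequence, lags ``-(N-1)..(N-1)``."""
        return np.concatenate([self.p[::-1], self.p[1:]])


@dataclass(frozen=True)
class SDPCertificate:
    """PSD certificate of spectral nonnegativity via the trace map.

    ``Z`` is an ``N x N`` positive-semidefinite matrix whose sums along
    super-diagonals reproduce ``p``: ``p(m) = sum_n Z[n, n+m]``.
    """

    Z: np.ndarray
    objective_value: float
    solver_status: str  # "optimal" | "inaccurate" | "infeasible"

    def trace_map(self) -> np.ndarray:
        """Super-diagonal sums of ``Z`` (should reproduce ``p``)."""
        N = self.Z.shape[0]
        return np.array([np.trace(self.Z, offset=m) for m in range(N)])

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.Z)[0])


@dataclass(frozen=True)
class WaveletFilterBank:
    """The four FIR filters of a two-channel orthogonal bank."""

    a0: np.ndarray
    a1: np.ndarray
    b0: np.ndarray
    b1: np.ndarray
    achieved_mssl: float
    spec: DesignSpec

    @property
    def N(self) -> int:
        return len(self.a0)

    @classmethod
    def from_lowpass(
        cls, a0: Sequence[float], spec: DesignSpec, achieved_mssl: float
    ) -> "WaveletFilterBank":
        """Build the full bank from ``a0`` by quadrature conjugation."""
        a0 = np.asarray(a0, dtype=float)
        N = len(a0)
        n = np.arange(N)
        a1 = (-1.0) ** n * a0[::-1]
        b0 = a0[::-1].copy()
        b1 = (-1.0) ** (n + 1) * a0
        return cls(a0=a0, a1=a1, b0=b0, b1=b1,
                   achieved_mssl=float(achieved_mssl), spec=spec)


@dataclass(frozen=True)
class VerificationReport:
    """Residuals of the defining identities of a designed bank."""

    pr_residual: float
    orthonormality_residual: float
    zm_residuals: np.ndarray
    mssl_by_quadrature: float

    def max_residual(self) -> float:
        zm = float(np.abs(self.zm_residuals).max()) if self.zm_residuals.size else 0.0
        return max(self.pr_residual, self.orthonormality_residual, zm)


# --------------------------------------------------------------------------
# objective
# --------------------------------------------------------------------------


def objective_vector(N: int) -> np.ndarray:
    """Linear MSSL functional ``s`` with ``sigma_f^2 = s . p`` at unit energy.

    ``s(0) = pi^2/3``; ``s(m) = -4/m^2`` for odd ``m``; ``s(m) = 0`` for
    even ``m >= 2``.  Follows from ``(1/pi) int_0^pi f^2 cos(m f) df =
    2 (-1)^m / m^2`` and the half-band structure (even lags of ``p``
    vanish, so their would-be positive weights never contribute).
    """
    if not isinstance(N, (int, np.integer)) or N < 2 or N % 2:
        raise ValueError(f"N must be an even integer >= 2, got {N!r}")
    s = np.zeros(N)
    s[0] = np.pi**2 / 3.0
    m = np.arange(1, N, 2)
    s[m] = -4.0 / m.astype(float) ** 2
    return s


def evaluate_product_spectrum(
    pf: ProductFilter, frequencies: Sequence[float]
) -> np.ndarray:
    """Evaluate ``P(e^{jf}) = p(0) + 2 sum_{m>=1} p(m) cos(m f)``.

    Real-valued by the symmetry of ``P``; frequencies must lie in
    ``[0, pi]``.
    """
    f = np.atleast_1d(np.asarray(frequencies, dtype=float))
    if f.size and (f.min() < -1e-12 or f.max() > np.pi + 1e-12):
        raise ValueError("frequencies must lie in [0, pi]")
    m = np.arange(1, pf.N)
    return pf.p[0] + 2.0 * np.cos(np.outer(f, m)) @ pf.p[1:]


# --------------------------------------------------------------------------
# product-filter optimization
# --------------------------------------------------------------------------


def _equality_system(N: int, M: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Regularity constraints on the free variables ``p(odd m)``.

    The ``2M`` zeros of ``P`` at ``z = -1`` are the vanishing of the even
    derivatives of ``P(e^{jf})`` at ``f = pi`` up to order ``2M - 2``.
    Under the half-band structure these reduce to

        sum_{odd m} p(m)            = 1/2          (k = 0)
        sum_{odd m} m^{2k} p(m)     = 0            (k = 1..M-1).

    Moment rows are scaled by ``m_max^{2k}`` for conditioning.
    """
    odd = np.arange(1, N, 2)
    rows = [np.ones(len(odd))]
    rhs = [0.5]
    for k in range(1, M):
        rows.append((odd / odd[-1]) ** (2 * k))
        rhs.append(0.0)
    return odd, np.asarray(rows, dtype=float), np.asarray(rhs, dtype=float)


def _binomial_filter(M: int) -> np.ndarray:
    """Coefficients of ``(z + 1)^M`` (the regularity factor of ``a0``)."""
    out = np.array([1.0])
    for _ in range(M):
        out = np.convolve(out, [1.0, 1.0])
    return out


def _dedupe_reciprocal(roots: np.ndarray) -> list[complex]:
    """One representative per reciprocal root pair, reflected inside.

    The roots of a symmetric nonnegative-spectrum polynomial come in
    para-conjugate pairs ``(r, 1/conj(r))``.  Reflecting every root to
    ``|r| <= 1`` maps each pair onto two near-identical points; greedy
    nearest-neighbor matching then keeps one of each.
    """
    inner = [r if abs(r) <= 1.0 else 1.0 / np.conj(r) for r in roots]
    kept: list[complex] = []
    unused = list(inner)
    while unused:
        r = unused.pop(0)
        if not unused:
            kept.append(r)
            break
        j = int(np.argmin([abs(u - r) for u in unused]))
        unused.pop(j)
        kept.append(r)
    return kept


def _least_squares_auto(fun, x0: np.ndarray):
    """``least_squares`` with LM when square/overdetermined, TRF otherwise."""
    method = "lm" if len(fun(x0)) >= len(x0) else "trf"
    return least_squares(fun, x0, method=method,
                         xtol=1e-15, ftol=1e-15, gtol=1e-15)


def _factor_initialize(
    p: np.ndarray, M: int, touch: tuple[float, ...]
) -> np.ndarray:
    """Best-effort reduced factor ``q`` with ``autocorr((z+1)^M q) ~= p``.

    The known structure is deflated before root finding: the ``2M`` zeros
    at ``z = -1`` and the optimizer-reported double zeros at the touch
    frequencies (by least-squares deconvolution, which is stable for
    unit-circle divisors).  The strictly positive remainder has
    well-separated reciprocal root pairs that are rooted and deduplicated
    robustly; a global Gauss-Newton fit of the autocorrelation then
    removes the rooting error.  The result may be inexact when ``p`` is
    only approximately factorizable -- callers decide how much residual
    to tolerate.
    """
    N = len(p)
    coef = np.concatenate([p[::-1], p[1:]])  # z^{N-1} P(z), degree 2N-2
    quads = [np.array([1.0, -2.0 * np.cos(ft), 1.0]) for ft in touch]
    known = _binomial_filter(2 * M)
    for quad in quads:
        known = np.convolve(known, np.convolve(quad, quad))
    n_rem = len(coef) - len(known) + 1
    conv_mat = np.zeros((len(coef), n_rem))
    for j in range(n_rem):
        conv_mat[j:j + len(known), j] = known
    rem = np.linalg.lstsq(conv_mat, coef, rcond=None)[0]
    rem = 0.5 * (rem + rem[::-1])

    if len(rem) > 1:
        kept = _dedupe_reciprocal(np.roots(rem))
        q0 = np.real(np.poly(kept))
    else:
        q0 = np.array([np.sqrt(max(float(rem[0]), 1e-16))])
    for quad in quads:
        q0 = np.convolve(q0, quad)

    b = _binomial_filter(M)
    a0 = np.convolve(b, q0)
    if len(a0) != N:
        raise FactorizationError(
            f"factor length {len(a0)} != {N}; root bookkeeping failed"
        )
    q0 = q0 / np.linalg.norm(a0)

    def residual(qq: np.ndarray) -> np.ndarray:
        aa = np.convolve(b, qq)
        return np.correlate(aa, aa, "full")[N - 1:] - p

    sol = _least_squares_auto(residual, q0)
    if np.abs(residual(sol.x)).max() < np.abs(residual(q0)).max():
        q0 = sol.x
    if np.convolve(b, q0).sum() < 0:
        q0 = -q0
    return q0


def _min_phase_factor(
    p: np.ndarray,
    M: int,
    eps: float,
    touch: tuple[float, ...] = (),
) -> np.ndarray:
    """Minimum-phase real factor ``a`` with ``autocorr(a) = p``.

    Wraps :func:`_factor_initialize` with the spectral-nonnegativity
    precondition and a hard residual check; the ``(z+1)^M`` regularity
    factor is carried exactly by construction.
    """
    N = len(p)
    f = np.linspace(0.0, np.pi, 1 << 13)
    spec = p[0] + 2.0 * np.cos(np.outer(f, np.arange(1, N))) @ p[1:]
    dip = float(spec.min())
    if dip < -max(eps, 1e-7):
        raise FactorizationError(
            f"product spectrum reaches {dip:.3e}; no real spectral factor exists"
        )
    q = _factor_initialize(p, M, touch)
    a = np.convolve(_binomial_filter(M), q)
    res = float(np.abs(np.correlate(a, a, "full")[N - 1:] - p).max())
    if res > 1e-7:
        raise FactorizationError(
            f"spectral factorization residual {res:.3e} exceeds tolerance"
        )
    if a.sum() < 0:
        a = -a
    return a


def _tap_space_refine(
    q0: np.ndarray, N: int, M: int
) -> tuple[np.ndarray, float]:
    """Refine the reduced filter on the exact orthonormality manifold.

    Minimizes the MSSL of ``a = (z+1)^M q`` subject to double-shift
    orthonormality (SLSQP from the convex-stage initialization, followed
    by a Gauss-Newton projection onto the constraints).  This removes the
    last microscopic infeasibility of the cutting-plane stage; regularity
    stays exact through the binomial factor.  Returns ``(q, constraint
    violation)``.
    """
    b = _binomial_filter(M)
    s = objective_vector(N)

    def acorr(q: np.ndarray) -> np.ndarray:
        a = np.convolve(b, q)
        return np.correlate(a, a, "full")[N - 1:]

    def obj(q: np.ndarray) -> float:
        return float(s @ acorr(q))

    def cons(q: np.ndarray) -> np.ndarray:
        even = acorr(q)[::2]
        target = np.zeros_like(even)
        target[0] = 1.0
        return even - target

    q = q0
    if N // 2 - M > 0:
        res = minimize(
            obj, q, constraints=[{"type": "eq", "fun": cons}],
            method="SLSQP", options={"maxiter": 500, "ftol": 1e-14},
        )
        cand = res.x
        if np.abs(cons(cand)).max() < 1e-6:
            q = cand
    sol = _least_squares_auto(cons, q)
    q = sol.x
    if np.convolve(b, q).sum() < 0:
        q = -q
    return q, float(np.abs(cons(q)).max())


def design_product_filter(
    spec: DesignSpec,
) -> tuple[ProductFilter, SDPCertificate]:
    """Solve the convex MSSL design problem over the product filter.

    Minimizes ``s . p`` subject to the half-band structure (imposed
    exactly by construction), the ``M`` regularity constraints, and
    spectral nonnegativity.  The semi-infinite nonnegativity constraint is
    handled by cutting-plane constraint exchange on the frequency axis,
    then a least-squares Newton polish that places the active double
    spectral zeros exactly.  The returned certificate's ``Z`` is the
    rank-one outer product of the minimum-phase spectral factor, which
    satisfies the trace parameterization of ``p`` identically.

    Returns
    -------
    (ProductFilter, SDPCertificate)
    """
    N, M = spec.filter_length, spec.zero_moments
    odd, Aeq, beq = _equality_system(N, M)
    nfree, neq = len(odd), len(beq)
    c = -4.0 / odd.astype(float) ** 2

    status = "optimal"
    touch: tuple[float, ...] = ()
    if neq == nfree:
        # maximal regularity: the equalities determine p uniquely
        x = np.linalg.solve(Aeq, beq)
    else:
        x, status = _cutting_plane(c, Aeq, beq, odd, spec)
        polished = _touch_point_polish(x, c, Aeq, beq, odd, spec)
        if polished is not None:
            x, touch = polished

    # convex-stage solution (may be microscopically infeasible at
    # degenerate optima); refine on the exact orthonormality manifold.
    # Two starts guard against local basins of the non-convex tap-space
    # polish: the factor of the convex solution, and the always-feasible
    # maximal-regularity (Daubechies) filter with its extra zeros at
    # z = -1 released into the free part.
    p_cvx = np.zeros(N)
    p_cvx[0] = 1.0
    p_cvx[odd] = x
    starts = [_factor_initialize(p_cvx, M, touch)]
    if M < N // 2:
        _, A_full, b_full = _equality_system(N, N // 2)
        x_db = np.linalg.solve(A_full, b_full)
        p_db = np.zeros(N)
        p_db[0] = 1.0
        p_db[odd] = x_db
        r_db = _factor_initialize(p_db, N // 2, ())
        starts.append(np.convolve(_binomial_filter(N // 2 - M), r_db))

    s = objective_vector(N)
    best: tuple[float, np.ndarray, float] | None = None
    for q0 in starts:
        q_ref, violation = _tap_space_refine(q0, N, M)
        a_ref = np.convolve(_binomial_filter(M), q_ref)
        sigma_ref = float(s @ np.correlate(a_ref, a_ref, "full")[N - 1:])
        if violation < 1e-8 and (best is None or sigma_ref < best[0]):
            best = (sigma_ref, a_ref, violation)
    if best is None:
        raise RuntimeError(
            "tap-space refinement failed to reach the orthonormality "
            "manifold from any start"
        )
    _, a, violation = best

    # the delivered product filter is the autocorrelation of the refined
    # taps with the half-band structure imposed exactly
    p = np.correlate(a, a, "full")[N - 1:]
    snap = float(np.abs(p[2::2]).max()) if N > 2 else 0.0
    p[0] = 1.0
    p[2::2] = 0.0
    # accuracy of the delivered solution is set by the refined taps, not
    # by how tightly the cutting-plane stage certified the lower bound
    status = (
        "optimal"
        if max(violation, snap) <= spec.solver_tolerance * 10
        else "inaccurate"
    )
    sigma = float(objective_vector(N) @ p)
    pf = ProductFilter(p=p, touch_frequencies=touch)
    Z = np.outer(a, a)
    cert = SDPCertificate(Z=Z, objective_value=sigma, solver_status=status)
    return pf, cert


def _cutting_plane(
    c: np.ndarray,
    Aeq: np.ndarray,
    beq: np.ndarray,
    odd: np.ndarray,
    spec: DesignSpec,
    max_iter: int = 15,
) -> tuple[np.ndarray, str]:
    """Kelley-style constraint exchange for ``P(e^{jf}) >= 0``."""
    nfree = len(odd)
    dense = np.linspace(0.0, np.pi, 1 << 15)
    C_dense = 2.0 * np.cos(np.outer(dense, odd))
    cuts = list(np.linspace(0.0, np.pi, 2049))
    x = None
    best_viol = -np.inf
    stall = 0
    for _ in range(max_iter):
        farr = np.asarray(cuts)
        res = linprog(
            c,
            A_ub=-2.0 * np.cos(np.outer(farr, odd)),
            b_ub=np.ones(len(farr)),
            A_eq=Aeq,
            b_eq=beq,
            bounds=[(None, None)] * nfree,
            method="highs",
        )
        if res.status == 2:
            raise InfeasibleDesignError(
                "linear program infeasible: the half-band, regularity and "
                "nonnegativity constraint families admit no product filter"
            )
        if res.status != 0:
            raise RuntimeError(f"LP solver failure: {res.message}")
        x = res.x
        P = 1.0 + C_dense @ x
        viol = float(P.min())
        if viol > -1e-10:
            return x, "optimal"
        if viol <= best_viol + 1e-12:
            stall += 1
            if stall >= 4:
                break
        else:
            best_viol = viol
            stall = 0

        def P_of(f: float) -> float:
            return 1.0 + 2.0 * float(np.sum(x * np.cos(odd * f)))

        mins = np.where(
            (P[1:-1] < P[:-2]) & (P[1:-1] < P[2:]) & (P[1:-1] < 0.0)
        )[0] + 1
        for j in mins:
            r = minimize_scalar(
                P_of,
                bounds=(dense[max(j - 1, 0)], dense[min(j + 1, len(dense) - 1)]),
                method="bounded",
                options={"xatol": 1e-14},
            )
            cuts.append(float(r.x))
    status = "optimal" if best_viol > -spec.solver_tolerance else "inaccurate"
    return x, status


def _touch_point_polish(
    x: np.ndarray,
    c: np.ndarray,
    Aeq: np.ndarray,
    beq: np.ndarray,
    odd: np.ndarray,
    spec: DesignSpec,
) -> tuple[np.ndarray, tuple[float, ...]] | None:
    """Pin the active double spectral zeros of the optimum exactly.

    At the semi-infinite optimum the spectrum touches zero at a finite set
    of interior frequencies (double zeros).  Solving the square/overdetermined
    system {equalities, P(f_t) = 0, P'(f_t) = 0} from the cutting-plane
    point removes the residual grid error.  Returns the polished solution,
    or None when no improvement is achieved.
    """
    nfree = len(odd)
    dense = np.linspace(0.0, np.pi, 1 << 15)
    C_dense = 2.0 * np.cos(np.outer(dense, odd))
    P = 1.0 + C_dense @ x

    def P_of(f: float) -> float:
        return 1.0 + 2.0 * float(np.sum(x * np.cos(odd * f)))

    cand = np.where((P[1:-1] <= P[:-2]) & (P[1:-1] <= P[2:]) & (P[1:-1] < 1e-4))[0] + 1
    refined: list[tuple[float, float]] = []
    for j in cand:
        r = minimize_scalar(
            P_of,
            bounds=(dense[max(j - 1, 0)], dense[min(j + 1, len(dense) - 1)]),
            method="bounded",
            options={"xatol": 1e-14},
        )
        f = float(r.x)
        if f < np.pi - 1e-6 and r.fun < 1e-4:
            if not refined or abs(f - refined[-1][0]) > 1e-3:
                refined.append((f, float(r.fun)))
    # A genuine interior touch zero stays small after dividing out the
    # 2M regularity zeros at pi; numerical-noise minima in the pi tail do
    # not.  The degree of P also bounds how many interior double zeros
    # can exist.
    M = len(beq)
    N = 2 * nfree
    g0 = 2.0 / 4.0**M
    scored = sorted(
        (
            (max(val, 1e-18) / (2.0 + 2.0 * np.cos(f)) ** M / g0, f)
            for f, val in refined
        ),
    )
    max_touch = min(nfree - len(beq), (N - 1 - M) // 2)
    touch = sorted(f for g, f in scored[:max_touch] if g < 1e-3)
    if not touch:
        return None

    nt = len(touch)

    def F(u: np.ndarray) -> np.ndarray:
        xx, ft = u[:nfree], u[nfree:]
        eqs = list(Aeq @ xx - beq)
        for f in ft:
            eqs.append(1.0 + 2.0 * np.sum(xx * np.cos(odd * f)))
            eqs.append(-2.0 * np.sum(xx * odd * np.sin(odd * f)))
        return np.asarray(eqs)

    sol = _least_squares_auto(F, np.concatenate([x, touch]))
    xs = sol.x[:nfree]
    if float(np.abs(F(sol.x)).max()) > 1e-9:
        return None
    Pd = 1.0 + C_dense @ xs
    if Pd.min() < -1e-11:
        return None
    if c @ xs > c @ x + 1e-7:
        return None
    return xs, tuple(float(ft) for ft in sol.x[nfree:])


# --------------------------------------------------------------------------
# factorization and verification
# --------------------------------------------------------------------------


def spectral_factorize(pf: ProductFilter, spec: DesignSpec) -> WaveletFilterBank:
    """Recover the full filter bank from a designed product filter.

    Chooses the minimum-phase factor (all roots inside or on the unit
    circle), which is deterministic and reproducible; unit-circle double
    roots are split evenly between the factor and its time reverse.  The
    DC gain convention is ``sum(a0) = sqrt(2)`` (``P(e^{j0}) = 2``).
    """
    a0 = _min_phase_factor(
        pf.p, spec.zero_moments, spec.psd_epsilon, pf.touch_frequencies
    )
    sigma = float(objective_vector(pf.N) @ pf.p)
    return WaveletFilterBank.from_lowpass(a0, spec, sigma)


def design_filter_bank(spec: DesignSpec) -> WaveletFilterBank:
    """One-call design: optimize the product filter, then factorize."""
    pf, cert = design_product_filter(spec)
    if cert.solver_status == "inaccurate":
        warnings.warn(
            "product-filter optimization reached only reduced accuracy "
            f"(status={cert.solver_status}); residuals may exceed "
            f"{spec.solver_tolerance:g}",
            RuntimeWarning,
            stacklevel=2,
        )
    return spectral_factorize(pf, spec)


def verify_filterbank(fb: WaveletFilterBank) -> VerificationReport:
    """Recompute the defining identities of a bank from its taps.

    * ``pr_residual``: max deviation of the even-lag autocorrelation of
      ``a0`` (equivalently of ``A0(z)B0(z) + A0(-z)B0(-z)``) from the
      perfect-reconstruction ideal of ``2 z^{-(N-1)}``.
    * ``orthonormality_residual``: max violation of double-shift
      orthonormality ``sum_n a0(n) a0(n-2m) = delta(m)``.
    * ``zm_residuals``: ``sum_m (-1)^m m^k a0(m)`` for ``k = 0..M-1``.
    * ``mssl_by_quadrature``: adaptive quadrature of the second spectral
      moment of ``|A0|^2``, normalized by the filter energy -- an oracle
      for the linear-functional value ``s . p``.
    """
    a0 = fb.a0
    N = len(a0)
    q = np.correlate(a0, a0, "full")[N - 1:]  # one-sided autocorrelation
    ortho = np.abs(q[0::2] - np.eye(1, len(q[0::2]), 0).ravel())
    orth_res = float(ortho.max())
    pr_res = 2.0 * orth_res  # P = 2 * autocorr in the DC-gain-2 convention

    M = fb.spec.zero_moments
    m = np.arange(N)
    zm = np.array(
        [float(np.sum((-1.0) ** m * m.astype(float) ** k * a0)) for k in range(M)]
    )

    E = float(np.sum(a0**2))

    def integrand(f: float) -> float:
        A = np.sum(a0 * np.exp(-1j * f * m))
        return f * f * float(np.abs(A) ** 2)

    val, _ = quad(integrand, 0.0, np.pi, limit=200)
    mssl = val / (np.pi * E)
    return VerificationReport(
        pr_residual=pr_res,
        orthonormality_residual=orth_res,
        zm_residuals=zm,
        mssl_by_quadrature=float(mssl),
    )


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------


def save_bank(fb: WaveletFilterBank, path: str | Path) -> None:
    """Write a bank to JSON (``.json``) or plain text (anything else).

    The text format has a ``# N M achieved_mssl`` header followed by one
    ``a0`` tap per line; the other three filters are re-derived on load.
    """
    path = Path(path)
    if path.suffix == ".json":
        payload = {
            "filter_length": fb.spec.filter_length,
            "zero_moments": fb.spec.zero_moments,
            "psd_epsilon": fb.spec.psd_epsilon,
            "solver_tolerance": fb.spec.solver_tolerance,
            "achieved_mssl": fb.achieved_mssl,
            "a0": fb.a0.tolist(),
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        lines = [f"# {fb.spec.filter_length} {fb.spec.zero_moments} {fb.achieved_mssl!r}"]
        lines += [repr(float(t)) for t in fb.a0]
        path.write_text("\n".join(lines) + "\n")


def load_bank(path: str | Path) -> WaveletFilterBank:
    """Inverse of :func:`save_bank`."""
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        spec = DesignSpec(
            filter_length=payload["filter_length"],
            zero_moments=payload["zero_moments"],
            psd_epsilon=payload.get("psd_epsilon", 1e-10),
            solver_tolerance=payload.get("solver_tolerance", 1e-9),
        )
        return WaveletFilterBank.from_lowpass(
            payload["a0"], spec, payload["achieved_mssl"]
        )
    lines = path.read_text().strip().splitlines()
    head = lines[0].lstrip("#").split()
    N, M, mssl = int(head[0]), int(head[1]), float(head[2])
    taps = [float(t) for t in lines[1:]]
    if len(taps) != N:
        raise ValueError(f"expected {N} taps, found {len(taps)} in {path}")
    return WaveletFilterBank.from_lowpass(taps, DesignSpec(N, M), mssl)
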