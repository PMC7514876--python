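"""Continuous-importance analysis of the allocation curves.

Letting the number of interface sections grow while their importance
degrees ``V`` sweep ``[0, 1]`` turns the per-section model into curves over
``V``: the correct-evaluation probability ``P(V)`` (a normalized
``exp(h(V))`` over the grid), the cognitive evaluations ``C_m(V) = P·V``
and ``C_p(V) = −P·ln(1−V)``, and their normalized allocation curves
``A_m`` and ``A_p``.

The printed limiting values (``P ≈ 0.006`` at the endpoints, ``0.012`` at
``V = 0.5``) correspond to a discretization of about one hundred sections:
on a uniform ``n``-point grid every ``P`` scales like ``1/n``, and the
2:1 ratio between the mid and endpoint values is exactly
``exp(h(0.5)) / exp(h(0)) = 2``. The default grid is 101 points (step
0.01, ``V = 0.5`` on-grid), which reproduces those values at 3-decimal
rounding; other grid sizes rescale ``P`` accordingly.

Two qualitative facts distinguish the models and are exposed here as
checks: ``C_p`` and ``A_p`` increase strictly with ``V`` (diverging at
``V = 1``), while ``C_m`` and ``A_m`` rise only up to a critical importance
``V* ≈ 0.7822`` — the root of ``1 + V·ln((1−V)/V) = 0`` — and fall beyond
it, so under the baseline a more important section can receive *less*
attention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import binary_entropy

__all__ = [
    "ContinuumGrid",
    "CriticalPointReport",
    "MonotonicityReport",
    "build_grid",
    "matsui_critical_value",
    "monotonicity_report",
    "export_curves",
]


@dataclass(frozen=True)
class ContinuumGrid:
    """Model curves sampled on a uniform importance grid over [0, 1].

    ``C_p`` and ``A_p`` hold ``inf`` at the ``V = 1`` endpoint (the proposed
    evaluation diverges there); ``A_p`` is normalized over the finite grid
    points. ``P`` and ``A_m`` each sum to one over the full grid.
    """

    V: np.ndarray
    h: np.ndarray
    exph: np.ndarray
    P: np.ndarray
    C_m: np.ndarray
    C_p: np.ndarray
    A_m: np.ndarray
    A_p: np.ndarray

    @property
    def n_points(self) -> int:
        return self.V.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "V": self.V,
                "h": self.h,
                "P": self.P,
                "C_m": self.C_m,
                "C_p": self.C_p,
                "A_m": self.A_m,
                "A_p": self.A_p,
            }
        )


def build_grid(n_points: int = 101) -> ContinuumGrid:
    """Evaluate all curves on a uniform ``n_points`` grid including 0 and 1.

    ``P`` is the normalized ``exp(h)`` over the grid, so its scale depends
    on ``n_points``; the shape (peak at 0.5, symmetric, 2:1 mid-to-end
    ratio) does not.
    """
    n = int(n_points)
    if n < 3:
        raise ValueError("need at least 3 grid points")
    V = np.linspace(0.0, 1.0, n)
    h = np.atleast_1d(binary_entropy(V))
    exph = np.exp(h)
    P = exph / exph.sum()
    C_m = P * V
    C_p = np.empty_like(V)
    C_p[:-1] = -P[:-1] * np.log1p(-V[:-1])
    C_p[-1] = np.inf
    A_m = C_m / C_m.sum()
    A_p = np.empty_like(V)
    A_p[:-1] = C_p[:-1] / C_p[:-1].sum()
    A_p[-1] = np.inf
    return ContinuumGrid(V=V, h=h, exph=exph, P=P, C_m=C_m, C_p=C_p, A_m=A_m, A_p=A_p)


@dataclass(frozen=True)
class CriticalPointReport:
    """Root of a curve's derivative: where the baseline stops increasing."""

    curve: str
    V_star: float
    derivative_residual: float
    bracket: tuple[float, float]


def _matsui_derivative_factor(v: float) -> float:
    # d/dV [V exp(h(V))] = exp(h(V)) * (1 + V ln((1-V)/V)); exp(h) > 0 so
    # the sign is carried entirely by this factor.
    return 1.0 + v * (np.log1p(-v) - np.log(v))


def matsui_critical_value(tol: float = 1e-12) -> CriticalPointReport:
    """Importance degree at which the baseline evaluation curve peaks.

    Solves ``1 + V·ln((1−V)/V) = 0`` on ``(0.5, 1)`` by bracketed root
    finding. The root is unique there: the factor is continuous, equals 1
    at ``V = 0.5`` and tends to ``−∞`` as ``V → 1``. Both ``C_m`` and
    ``A_m`` share this stationary point since normalization by a positive
    constant does not move it. Rounds to 0.7822.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    lo, hi = 0.5, 1.0 - 1e-9
    root = float(brentq(_matsui_derivative_factor, lo, hi, xtol=tol))
    return CriticalPointReport(
        curve="C_m",
        V_star=root,
        derivative_residual=abs(_matsui_derivative_factor(root)),
        bracket=(lo, hi),
    )


@dataclass(frozen=True)
class MonotonicityReport:
    """Shape checks of the sampled curves; violations hold grid indices."""

    proposed_C_increasing: bool
    proposed_A_increasing: bool
    matsui_unimodal: bool
    matsui_mode_V: float
    P_peak_at_half: bool
    P_symmetric: bool
    first_violation: str | None = None


def monotonicity_report(grid: ContinuumGrid) -> MonotonicityReport:
    """Verify the qualitative curve shapes on a built grid.

    The proposed curves must increase strictly (the infinite ``V = 1``
    sentinel is excluded); the baseline curves must rise before the
    critical importance and fall after it; ``P`` must peak at ``V = 0.5``
    and be symmetric under ``V -> 1 - V``.
    """
    violation: str | None = None

    cp = grid.C_p[:-1]
    ap = grid.A_p[:-1]
    cp_inc = bool(np.all(np.diff(cp) > 0))
    ap_inc = bool(np.all(np.diff(ap) > 0))
    if not cp_inc and violation is None:
        violation = f"C_p not increasing at index {int(np.argmin(np.diff(cp) > 0))}"
    if not ap_inc and violation is None:
        violation = f"A_p not increasing at index {int(np.argmin(np.diff(ap) > 0))}"

    v_star = matsui_critical_value().V_star
    before = grid.V <= v_star
    cm_ok = bool(
        np.all(np.diff(grid.C_m[before]) > 0) and np.all(np.diff(grid.C_m[~before]) < 0)
    )
    am_ok = bool(
        np.all(np.diff(grid.A_m[before]) > 0) and np.all(np.diff(grid.A_m[~before]) < 0)
    )
    unimodal = cm_ok and am_ok
    if not unimodal and violation is None:
        violation = "C_m/A_m not unimodal about the critical value"
    mode_V = float(grid.V[int(np.argmax(grid.C_m))])

    peak = bool(grid.P.max() <= grid.P[np.argmin(np.abs(grid.V - 0.5))] + 1e-15)
    symmetric = bool(np.allclose(grid.P, grid.P[::-1], rtol=0.0, atol=1e-15))
    if not peak and violation is None:
        violation = "P does not peak at V=0.5"
    if not symmetric and violation is None:
        violation = "P not symmetric"

    return MonotonicityReport(
        proposed_C_increasing=cp_inc,
        proposed_A_increasing=ap_inc,
        matsui_unimodal=unimodal,
        matsui_mode_V=mode_V,
        P_peak_at_half=peak,
        P_symmetric=symmetric,
        first_violation=violation,
    )


def export_curves(grid: ContinuumGrid, path: str | Path, plot: str | Path | None = None) -> None:
    """Write the sampled curves as tidy CSV; infinities render as ``inf``.

    If ``plot`` is given, also saves a two-panel figure (evaluation and
    allocation curves) to that path; matplotlib is imported lazily.
    """
    df = grid.to_frame()
    df.to_csv(path, index=False)
    if plot is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
        fin = np.isfinite(grid.C_p)
        ax1.plot(grid.V, grid.C_m, label="C_m (baseline)")
        ax1.plot(grid.V[fin], grid.C_p[fin], label="C_p (proposed)")
        ax1.set_xlabel("V")
        ax1.set_ylabel("cognitive evaluation")
        ax1.legend()
        ax2.plot(grid.V, grid.A_m, label="A_m")
        ax2.plot(grid.V[fin], grid.A_p[fin], label="A_p")
        ax2.plot(grid.V, grid.P, ":", label="P")
        ax2.set_xlabel("V")
        ax2.set_ylabel("fraction")
        ax2.legend()
        fig.tight_layout()
        fig.savefig(plot, dpi=150)
        plt.close(fig)
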