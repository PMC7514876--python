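"""Closed-form attention allocation math.

The model predicts what fraction of a supervisor's visual attention each
interface section receives, from the sections' fuzzy importance degrees
``V_i`` alone. Two cognitive tendencies combine:

* **Fuzziness tendency** — the probability ``P_i`` that the supervisor
  correctly evaluates section ``i``. Maximizing the hybrid entropy
  ``S = Σ −P_i ln P_i + Σ P_i h(V_i)`` (probabilistic entropy plus expected
  fuzzy binary entropy) over the probability simplex gives the closed form
  ``P_i ∝ exp(h(V_i))`` — a softmax of the binary entropy, peaked at the
  fuzziest sections (``V = 0.5``). The maximized value ``S_max`` is the
  supervisor's mental entropy.
* **Importance tendency** — the value priority ``V'_i = −ln(1 − V_i)``,
  constructed like an information amount so that attention grows without
  bound as importance approaches 1.

The cognitive evaluation is ``C_i = P_i · V'_i`` for the proposed model, or
``C_i = P_i · V_i`` for the earlier Matsui-style fuzzy baseline (which is
non-monotone in ``V``, peaking near ``V ≈ 0.78``). Normalizing ``C`` gives
the predicted fractional attention ``A_i = C_i / Σ_j C_j``.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .profile import ValueProfile

__all__ = [
    "Model",
    "EvaluationProbabilities",
    "AllocationResult",
    "info_amount",
    "binary_entropy",
    "value_priority",
    "correct_eval_prob",
    "hybrid_entropy",
    "mental_entropy",
    "cognitive_evaluation",
    "allocate",
    "invert_allocation",
]

_SUM_TOL = 1e-12


class Model(str, enum.Enum):
    """Which cognitive-evaluation rule to use."""

    PROPOSED = "proposed"  # C_i = -P_i ln(1 - V_i)
    MATSUI = "matsui"      # C_i = P_i V_i


def _as_model(model: "Model | str") -> Model:
    return Model(model) if not isinstance(model, Model) else model


def info_amount(p: float | np.ndarray) -> float | np.ndarray:
    """Shannon information amount ``-ln p`` (nats) of an event with probability ``p``.

    Monotone decreasing; an inevitable event (``p = 1``) carries no
    information. ``p`` must lie in ``(0, 1]``.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr > 1.0):
        raise ValueError("probability must lie in (0, 1]")
    out = -np.log(arr)
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def binary_entropy(v: float | np.ndarray) -> float | np.ndarray:
    """Fuzzy (binary) entropy ``h(v) = -v ln v - (1-v) ln(1-v)`` in nats.

    Uses the limit convention ``0 ln 0 = 0`` so ``h(0) = h(1) = 0``;
    symmetric about the maximum ``ln 2`` at ``v = 0.5``.
    """
    arr = np.atleast_1d(np.asarray(v, dtype=float))
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError("membership degree must lie in [0, 1]")
    out = np.zeros_like(arr)
    interior = (arr > 0.0) & (arr < 1.0)
    a = arr[interior]
    out[interior] = -a * np.log(a) - (1.0 - a) * np.log1p(-a)
    return float(out[0]) if np.isscalar(v) or np.asarray(v).ndim == 0 else out


def value_priority(v: float | np.ndarray) -> float | np.ndarray:
    """Value priority ``F(v) = -ln(1 - v)`` in nats.

    Strictly increasing from ``F(0) = 0`` and diverging as ``v → 1``, so
    that attention demand grows without bound for near-certain importance.
    Requires ``0 <= v < 1``.
    """
    arr = np.asarray(v, dtype=float)
    if np.any(arr < 0.0) or np.any(arr >= 1.0):
        raise ValueError("membership degree must lie in [0, 1) for value priority")
    out = -np.log1p(-arr)
    return float(out) if np.isscalar(v) or arr.ndim == 0 else out


def correct_eval_prob(profile: ValueProfile) -> "EvaluationProbabilities":
    """Maximum-hybrid-entropy probabilities of correct evaluation.

    ``P_i = exp(h(V_i)) / Σ_j exp(h(V_j))`` — the simplex point at which the
    hybrid entropy attains its maximum. Equal importance degrees map to a
    uniform ``P``; ``V`` and ``1 - V`` receive identical ``P``.
    """
    w = np.exp(binary_entropy(profile.V))
    return EvaluationProbabilities(w / w.sum())


@dataclass(frozen=True)
class EvaluationProbabilities:
    """Per-section correct-evaluation probabilities summing to one."""

    P: np.ndarray

    def __init__(self, P: Sequence[float]) -> None:
        arr = np.asarray(P, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("P must be a non-empty vector")
        if np.any(arr <= 0.0) or np.any(arr > 1.0):
            raise ValueError("each P_i must lie in (0, 1]")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"P must sum to 1, got {arr.sum()!r}")
        arr = arr / arr.sum()
        arr.setflags(write=False)
        object.__setattr__(self, "P", arr)

    def __len__(self) -> int:
        return self.P.size


def hybrid_entropy(P: EvaluationProbabilities | Sequence[float], profile: ValueProfile) -> float:
    """Hybrid entropy ``S = Σ −P_i ln P_i + Σ P_i h(V_i)`` in nats.

    At ``P = correct_eval_prob(profile)`` this equals the mental entropy
    ``S_max = ln Σ_j exp(h(V_j))``, the maximum over the simplex.
    """
    p = P.P if isinstance(P, EvaluationProbabilities) else np.asarray(P, dtype=float)
    if p.size != len(profile):
        raise ValueError("P and profile lengths differ")
    h = binary_entropy(profile.V)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0.0, p * np.log(np.where(p > 0.0, p, 1.0)), 0.0)
    return float(-plogp.sum() + (p * h).sum())


def mental_entropy(profile: ValueProfile) -> float:
    """``S_max = ln Σ_j exp(h(V_j))``: the hybrid entropy at its maximizer."""
    return float(np.log(np.exp(binary_entropy(profile.V)).sum()))


def cognitive_evaluation(
    P: EvaluationProbabilities | Sequence[float],
    profile: ValueProfile,
    model: Model | str = Model.PROPOSED,
) -> np.ndarray:
    """Per-section cognitive evaluation ``C_i``.

    Proposed: ``C_i = −P_i ln(1 − V_i)``; Matsui baseline: ``C_i = P_i V_i``.
    Sections with ``V = 1`` (admitted only by a permissive profile) receive
    ``C = inf`` under the proposed rule, reflecting its divergent limit.
    """
    m = _as_model(model)
    p = P.P if isinstance(P, EvaluationProbabilities) else np.asarray(P, dtype=float)
    if p.size != len(profile):
        raise ValueError("P and profile lengths differ")
    if m is Model.MATSUI:
        return p * profile.V
    v = profile.V
    c = np.empty_like(v)
    unit = v >= 1.0
    c[~unit] = -p[~unit] * np.log1p(-v[~unit])
    c[unit] = np.inf
    return c


@dataclass(frozen=True)
class AllocationResult:
    """Full per-section model output for one profile and model variant.

    Attributes
    ----------
    model : Model
        Which cognitive-evaluation rule produced the result.
    labels, V : section labels and importance degrees.
    h : binary entropy ``h(V_i)`` (nats).
    P : correct-evaluation probabilities (max-entropy closed form).
    V_prime : value priority ``-ln(1-V_i)`` (nats; ``inf`` at ``V=1``).
    C : cognitive evaluation.
    A : fractional attention, summing to one.
    S : hybrid entropy at ``P`` — the mental entropy ``S_max``.
    """

    model: Model
    labels: tuple[str, ...]
    V: np.ndarray
    h: np.ndarray
    P: np.ndarray
    V_prime: np.ndarray
    C: np.ndarray
    A: np.ndarray
    S: float
    S_is_max: bool = True

    @property
    def A_percent(self) -> np.ndarray:
        return self.A * 100.0

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-section table."""
        return pd.DataFrame(
            {
                "label": self.labels,
                "V": self.V,
                "h": self.h,
                "P": self.P,
                "V_prime": self.V_prime,
                "C": self.C,
                "A_fraction": self.A,
                "A_percent": self.A_percent,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "model": self.model.value,
            "S": self.S,
            "S_is_max": self.S_is_max,
            "sections": self.to_frame().replace([np.inf], "inf").to_dict("records"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def allocate(profile: ValueProfile, model: Model | str = Model.PROPOSED) -> AllocationResult:
    """Predict fractional attention ``A_i = C_i / Σ_j C_j`` for a profile.

    Permutation-equivariant and normalized to ``Σ A_i = 1``. A profile that
    is all zeros under the proposed rule has ``Σ C = 0`` and raises, since
    the allocation is undefined. Sections with ``V = 1`` (permissive
    profiles only) absorb all attention, split equally among themselves —
    the model's limiting behavior as ``V → 1``.
    """
    m = _as_model(model)
    P = correct_eval_prob(profile)
    h = np.atleast_1d(binary_entropy(profile.V))
    unit = profile.V >= 1.0
    v_prime = np.full_like(profile.V, np.inf)
    v_prime[~unit] = -np.log1p(-profile.V[~unit])
    C = cognitive_evaluation(P, profile, m)
    if unit.any() and m is Model.PROPOSED:
        A = np.where(unit, 1.0 / unit.sum(), 0.0)
    else:
        total = C.sum()
        if total <= 0.0:
            raise ValueError(
                "allocation undefined: all cognitive evaluations are zero "
                "(every V_i = 0 under the proposed model)"
            )
        A = C / total
    return AllocationResult(
        model=m,
        labels=profile.labels,
        V=profile.V.copy(),
        h=h,
        P=P.P.copy(),
        V_prime=v_prime,
        C=C,
        A=A,
        S=hybrid_entropy(P, profile),
    )


def _g(v: np.ndarray) -> np.ndarray:
    """Unnormalized proposed-model evaluation g(v) = exp(h(v)) * (-ln(1-v)).

    Strictly increasing on [0, 1): both the attention share and its
    inversion are monotone in v, which makes per-section inversion unique.
    """
    return np.exp(np.atleast_1d(binary_entropy(v))) * (-np.log1p(-np.asarray(v, dtype=float)))


def invert_allocation(
    A: Sequence[float],
    anchor: tuple[int, float],
    labels: Sequence[str] | None = None,
    tol: float = 1e-12,
) -> ValueProfile:
    """Recover a value profile whose proposed-model allocation equals ``A``.

    The forward map ``V -> A`` is scale-free: allocations only determine the
    per-section values ``g(V_i) = exp(h(V_i))·(−ln(1−V_i))`` up to a common
    factor, so a one-parameter family of profiles shares each ``A``. The
    ``anchor = (index, V_value)`` pins that scale by asserting the true
    importance of one section; each remaining ``V_i`` then solves
    ``g(V_i) = s·A_i`` uniquely, because ``g`` is strictly increasing.
    """
    a = np.asarray(A, dtype=float)
    if a.ndim != 1 or a.size == 0:
        raise ValueError("A must be a non-empty vector")
    if np.any(a <= 0.0):
        raise ValueError("target fractions must be positive")
    if abs(a.sum() - 1.0) > 1e-9:
        raise ValueError(f"target fractions must sum to 1, got {a.sum()!r}")
    k, v_k = anchor
    k = int(k)
    if not (0 <= k < a.size):
        raise ValueError("anchor index out of range")
    if not (0.0 < v_k < 1.0):
        raise ValueError("anchor V must lie in (0, 1)")
    scale = float(_g(np.array([v_k]))[0]) / a[k]

    hi = 1.0 - 1e-15
    g_hi = float(_g(np.array([hi]))[0])
    V = np.empty_like(a)
    for i, target in enumerate(scale * a):
        if i == k:
            V[i] = v_k
            continue
        if target > g_hi:
            raise ValueError(
                f"infeasible anchor: section {i} requires g={target:.3g} "
                f"beyond the representable range"
            )
        V[i] = brentq(lambda v: float(_g(np.array([v]))[0]) - target, 0.0, hi, xtol=tol)
    labels = list(labels) if labels is not None else [f"section_{i}" for i in range(a.size)]
    return ValueProfile(labels=labels, V=V)
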