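"""Flexibility score Q for a pocket group, flexibility class and Vg.

For the m×m similarity sub-matrix of a valid pocket group (m ≥ 3):

* σ_i — population standard deviation of row i (spatial variation seen from
  reference pocket i);
* S — mean of the σ_i; larger S means the pockets wander more;
* P̄ — grand mean of the sub-matrix; larger P̄ means the pockets overlap more;
* Γ — topology-change term: the mean over pockets of the absolute difference
  between the pocket's sphericity Ψ_i and the sphericity of its "difference
  pocket", π^(1/3)·(6·|V_i−V̄|)^(2/3) / (A_i−Ā);
* Q — the flexibility score, by default the quotient (S/P̄)/Γ.

Q classifies a group as rigidity (Q < 0.30), intermediate (0.30 ≤ Q < 0.60)
or flexibility (Q ≥ 0.60).  The overlapping volume Vg = V̄ × P̄ stratifies
groups into small (≤ 500 Å³), medium (≤ 1500 Å³) and large (≤ 7200 Å³) bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .pocket_detect import PocketMetrics

__all__ = [
    "FlexibilityResult",
    "spatial_terms",
    "topology_term",
    "flexibility_Q",
    "classify_flexibility",
    "overlapping_volume",
    "score_group",
]

#: |A_i − Ā| below this (Å²) is treated as zero in Γ's degenerate terms
AREA_EPSILON = 1e-9


@dataclass
class FlexibilityResult:
    sigma_i: list[float]
    S: float
    Pbar: float
    Gamma: float
    Q: float
    flex_class: str
    Vbar: float
    Abar: float
    Vg: float
    size_class: str


def spatial_terms(sub_matrix: np.ndarray) -> tuple[np.ndarray, float, float]:
    """(σ_i, S, P̄) of an m×m similarity sub-matrix.

    σ_i is the population (÷m) standard deviation of row i about its own
    row mean; S is the mean of the σ_i; P̄ the grand mean of all m² entries.
    """
    sub = np.asarray(sub_matrix, dtype=float)
    if sub.ndim != 2 or sub.shape[0] != sub.shape[1]:
        raise ValueError("similarity sub-matrix must be square")
    m = sub.shape[0]
    if m < 3:
        raise ValueError(f"invalid group: m = {m} < 3")
    sigma_i = sub.std(axis=1, ddof=0)
    return sigma_i, float(sigma_i.mean()), float(sub.mean())


def topology_term(
    metrics: list[PocketMetrics],
    gamma_form: str = "sphericity",
) -> float:
    """Γ, the mean absolute sphericity change across the group's pockets.

    Each term compares Ψ_i with the sphericity of the "difference pocket"
    of volume |V_i − V̄| and signed area (A_i − Ā).  When A_i ≈ Ā the
    quotient is taken as zero and the term contributes |Ψ_i|.
    ``gamma_form='literal'`` drops the sphericity constant and instead uses
    |V_i − V̄|^(2/3) / (6·(A_i − Ā)).
    """
    if len(metrics) < 3:
        raise ValueError("invalid group: need m >= 3 pockets")
    V = np.array([mt.Vp for mt in metrics])
    A = np.array([mt.Ap for mt in metrics])
    psi = np.array([mt.psi for mt in metrics])
    dV = np.abs(V - V.mean())
    dA = A - A.mean()

    terms = np.empty(len(metrics))
    for i in range(len(metrics)):
        if abs(dA[i]) < AREA_EPSILON:
            quot = 0.0
        elif gamma_form == "sphericity":
            quot = np.pi ** (1 / 3) * (6 * dV[i]) ** (2 / 3) / dA[i]
        elif gamma_form == "literal":
            quot = dV[i] ** (2 / 3) / (6 * dA[i])
        else:
            raise ValueError(f"unknown gamma_form {gamma_form!r}")
        terms[i] = abs(psi[i] - quot)
    return float(terms.mean())


def flexibility_Q(
    S: float,
    Pbar: float,
    Gamma: float,
    form: str = "quotient",
) -> float:
    """Flexibility score Q; larger Q means a more flexible pocket group.

    The default quotient form is Q = (S/P̄)/Γ; ``form='product'`` gives
    Q = (S/P̄)·Γ.  S = 0 (identical pockets) yields Q = 0 in both forms.
    """
    if not Pbar > 0:
        raise ValueError("Pbar must be positive")
    if S == 0:
        return 0.0
    if form == "quotient":
        if Gamma <= 0:
            raise ValueError("degenerate group: quotient form needs Gamma > 0")
        return (S / Pbar) / Gamma
    if form == "product":
        return (S / Pbar) * Gamma
    raise ValueError(f"unknown Q form {form!r}")


def classify_flexibility(Q: float) -> str:
    """rigidity (Q < 0.30) / intermediate (0.30 ≤ Q < 0.60) / flexibility."""
    if Q < 0:
        raise ValueError("Q must be non-negative")
    if Q < 0.30:
        return "rigidity"
    if Q < 0.60:
        return "intermediate"
    return "flexibility"


def overlapping_volume(Vbar: float, Pbar: float) -> tuple[float, str]:
    """Vg = V̄ × P̄ and its size bin (small ≤ 500 < medium ≤ 1500 < large)."""
    if not Vbar > 0 or not 0 < Pbar <= 1:
        raise ValueError("need Vbar > 0 and 0 < Pbar <= 1")
    Vg = Vbar * Pbar
    if Vg <= 500:
        size = "small"
    elif Vg <= 1500:
        size = "medium"
    else:
        size = "large"
        if Vg > 7200:
            warnings.warn(
                f"Vg = {Vg:.0f} Å³ exceeds the calibrated range (7200 Å³)",
                stacklevel=2,
            )
    return Vg, size


def score_group(
    sub_matrix: np.ndarray,
    metrics: list[PocketMetrics],
    gamma_form: str = "sphericity",
    q_form: str = "quotient",
) -> FlexibilityResult:
    """Full flexibility report for one valid pocket group."""
    sigma_i, S, Pbar = spatial_terms(sub_matrix)
    Gamma = topology_term(metrics, gamma_form=gamma_form)
    Q = flexibility_Q(S, Pbar, Gamma, form=q_form)
    Vbar = float(np.mean([mt.Vp for mt in metrics]))
    Abar = float(np.mean([mt.Ap for mt in metrics]))
    Vg, size_class = overlapping_volume(Vbar, Pbar)
    return FlexibilityResult(
        sigma_i=[float(s) for s in sigma_i],
        S=S,
        Pbar=Pbar,
        Gamma=Gamma,
        Q=Q,
        flex_class=classify_flexibility(Q),
        Vbar=Vbar,
        Abar=Abar,
        Vg=Vg,
        size_class=size_class,
    )
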