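"""Selection against frameshift sites and their accumulation dynamics.

The balance of selection and drift is summarised by Kimura's scaled
selection coefficient S = 4*s*Ne.  The observed substitution rate of a
variant with scaled selection S relative to the neutral mutation rate mu is

    u / mu = S / (1 - exp(-S)),

which tends to 1 as S -> 0.  Because the gain of a frameshift site and its
loss have opposite fitness effects of equal magnitude, and thymine insertion
and deletion rates at stop-codon contexts are equal, the ratio of observed
gain and loss probabilities inverts to

    S = ln(P_gain / P_loss).

Per-genome frameshift-site counts follow a logistic birth-death equation

    dF = (K - F) u_gain dt - F u_loss dt,

with K the (constant) number of suitable gain contexts.  Its solution is
F(t) = [F(0) - A] exp(-t (u_gain + u_loss)) + A with the equilibrium
asymptote A = K u_gain / (u_gain + u_loss).  Time is measured in nucleotide
substitutions per site, the same unit as the tree branch lengths from which
the rates are derived.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SelectionEstimate",
    "DynamicsModel",
    "scaled_selection",
    "normalized_rate",
    "prob_to_rate",
    "equilibrium",
    "project",
    "time_to_fraction",
    "genome_scale",
    "lag_load",
]


@dataclass(frozen=True)
class SelectionEstimate:
    p_gain: float
    p_loss: float
    S: float
    is_bound: bool = False
    ci_low: float | None = None
    ci_high: float | None = None


def scaled_selection(
    p_gain: float,
    p_loss: float,
    is_bound: bool = False,
    ci: tuple[float, float] | None = None,
) -> SelectionEstimate:
    """S = ln(P_gain / P_loss); requires both probabilities positive.

    Zero-count probabilities must be replaced upstream by pseudo-count
    bounds, in which case ``is_bound`` marks the estimate as a bound.
    """
    if not (0 < p_gain <= 1) or not (0 < p_loss <= 1):
        raise ValueError("P_gain and P_loss must lie in (0, 1]")
    s = math.log(p_gain / p_loss)
    lo, hi = ci if ci is not None else (None, None)
    return SelectionEstimate(p_gain, p_loss, s, is_bound, lo, hi)


def normalized_rate(S: float) -> float:
    """u/mu = S / (1 - exp(-S)), continuously extended to 1 at S = 0."""
    if S == 0.0:
        return 1.0
    denom = -math.expm1(-S)
    return S / denom


def prob_to_rate(P: float, total_branch_length: float) -> float:
    """Event probability over the observed tree -> rate per unit branch length."""
    if total_branch_length <= 0:
        raise ValueError("total branch length must be positive")
    if P < 0:
        raise ValueError("probability must be nonnegative")
    return P / total_branch_length


def equilibrium(K: float, u_gain: float, u_loss: float) -> float:
    """Asymptotic frameshift-site number A = K u_gain / (u_gain + u_loss)."""
    if u_gain < 0 or u_loss < 0:
        raise ValueError("rates must be nonnegative")
    if u_gain + u_loss == 0:
        raise ValueError("equilibrium undefined when both rates are zero")
    return K * u_gain / (u_gain + u_loss)


def project(F0: float, K: float, u_gain: float, u_loss: float, t) -> np.ndarray | float:
    """Closed-form F(t) of the gain/loss ODE; accepts scalar or array t."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be nonnegative")
    total = u_gain + u_loss
    if total == 0:
        out = np.full_like(t_arr, float(F0))
        return out if out.ndim else float(out)
    A = equilibrium(K, u_gain, u_loss)
    out = (F0 - A) * np.exp(-total * t_arr) + A
    return out if out.ndim else float(out)


def time_to_fraction(
    F0: float, K: float, u_gain: float, u_loss: float, q: float = 0.95
) -> float:
    """Time until F(t) reaches the fraction q of the asymptote A.

    Returns 0.0 when the current count already meets or exceeds q*A.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    A = equilibrium(K, u_gain, u_loss)
    if F0 >= q * A:
        return 0.0
    return math.log((A - F0) / ((1 - q) * A)) / (u_gain + u_loss)


def genome_scale(
    eq_fs_per_gene: float,
    n_genes: float,
    eq_fs_per_coding_bp: float | None = None,
    coding_bp: float | None = None,
) -> dict:
    """Project sample-level equilibrium frequencies to per-genome counts.

    Two estimators: equilibrium FSs per gene times the genome's gene count,
    and (if provided) equilibrium FS density per coding bp times the coding
    genome length.  Both are reported together with their ratio.
    """
    if n_genes <= 0:
        raise ValueError("genome totals must be positive")
    by_genes = eq_fs_per_gene * n_genes
    out = {"per_genome_by_genes": by_genes}
    if eq_fs_per_coding_bp is not None and coding_bp is not None:
        if coding_bp <= 0:
            raise ValueError("genome totals must be positive")
        by_bp = eq_fs_per_coding_bp * coding_bp
        out["per_genome_by_coding_bp"] = by_bp
        out["estimator_ratio"] = by_genes / by_bp if by_bp else float("inf")
    return out


def lag_load(S_mag: float, Ne: float, F: float) -> float:
    """Net lag load L = 1 - (1 - |S|/Ne)^F of F independent deleterious sites.

    ``S_mag`` is the deleterious magnitude of the scaled selection
    coefficient (|S| = 4|s|Ne, so |S|/Ne = 4|s|).
    """
    if S_mag < 0:
        raise ValueError("S_mag is a magnitude and must be >= 0")
    if Ne <= S_mag:
        raise ValueError("require Ne > S_mag")
    if F < 0:
        raise ValueError("F must be >= 0")
    return -math.expm1(F * math.log1p(-S_mag / Ne))


@dataclass
class DynamicsModel:
    """Gain/loss dynamics of frameshift sites for one species or cohort."""

    K: float
    F0: float
    u_gain: float
    u_loss: float

    @property
    def A(self) -> float:
        return equilibrium(self.K, self.u_gain, self.u_loss)

    @property
    def b(self) -> float:
        return self.K * self.u_gain

    @property
    def fold_change(self) -> float:
        return self.A / self.F0 if self.F0 > 0 else float("inf")

    def F(self, t) -> np.ndarray | float:
        return project(self.F0, self.K, self.u_gain, self.u_loss, t)

    def t_to_fraction(self, q: float = 0.95) -> float:
        return time_to_fraction(self.F0, self.K, self.u_gain, self.u_loss, q)

    def summary(self) -> dict:
        return {
            "K": self.K,
            "F0": self.F0,
            "u_gain": self.u_gain,
            "u_loss": self.u_loss,
            "A": self.A,
            "fold_change": self.fold_change,
            "t95": self.t_to_fraction(0.95),
        }
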