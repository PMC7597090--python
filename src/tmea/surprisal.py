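"""Surprisal analysis of log-abundance matrices by singular value decomposition.

The model writes the log abundance of entity i at time t as a baseline term
plus a small number of constraint terms,

    ln X_i(t) = G_i0 lambda_0(t) + sum_{alpha>=1} G_ialpha lambda_alpha(t),

where G_.alpha are per-entity weights (orthonormal across entities) and
lambda_alpha(t) are time-dependent constraint potentials (Lagrange
multipliers). The thin SVD ``L = U S V^T`` realises this decomposition with
G = U and lambda_alpha(t) = sigma_alpha V_talpha; the dominant component
alpha = 0 is the baseline state of minimum free energy, and each further
component is a constraint preventing the system from relaxing to it. The
surprisal of an observation is the negated deviation from the baseline,
-(L_it - G_i0 lambda_0(t)) = -sum_{alpha>=1} G_ialpha lambda_alpha(t).

Free energy attributable to constraint alpha at time t is

    F_alpha(t) = -lambda_alpha(t) * sum_i X_i(t) G_ialpha,

and the total work done on the system is the sum over constraints alpha >= 1.

SVD leaves the sign of each (U column, V column) pair arbitrary; a fixed
sign convention (see :func:`decompose`) makes the decomposition a
deterministic function of its input, which downstream Monte Carlo testing
requires for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from tmea.io import AbundanceMatrix


@dataclass
class LogMatrix:
    """Natural-log abundance matrix L_it = ln(X_i(t) + pseudocount)."""

    entity_ids: list[str]
    condition_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.entity_ids), len(self.condition_labels)):
            raise ValueError("log matrix shape does not match labels")
        if not np.all(np.isfinite(self.values)):
            i = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite log abundance for entity {self.entity_ids[i[0]]!r}"
            )


@dataclass
class SurprisalDecomposition:
    """Weights G (entities x components), potentials Lambda (components x conditions).

    Component alpha = 0 is the baseline; alpha >= 1 are constraints.
    ``weights`` columns are orthonormal; ``potentials`` row alpha equals
    sigma_alpha * V[:, alpha] so that ``weights @ potentials`` reconstructs
    the log matrix exactly when all components are kept.
    """

    weights: np.ndarray
    potentials: np.ndarray
    singular_values: np.ndarray
    entity_ids: list[str]
    condition_labels: list[str]

    @property
    def n_components(self) -> int:
        return len(self.singular_values)

    @property
    def max_constraint(self) -> int:
        """Largest valid constraint index r (components are 0..r)."""
        return self.n_components - 1

    def constraint_weights(self, alpha: int) -> dict[str, float]:
        """Per-entity weight map G_.alpha for one component."""
        self._check_component(alpha)
        col = self.weights[:, alpha]
        return dict(zip(self.entity_ids, col.tolist()))

    def _check_component(self, alpha: int) -> None:
        if not 0 <= alpha <= self.max_constraint:
            raise ValueError(
                f"component index {alpha} out of range 0..{self.max_constraint}"
            )


@dataclass
class FreeEnergyTable:
    """Per-constraint free energies F_alpha(t) and their total."""

    per_constraint: np.ndarray
    total: np.ndarray
    constraint_indices: list[int]
    condition_labels: list[str]


@dataclass
class ImportanceSpectrum:
    """Singular values and relative importance losses between consecutive ones.

    ``relative_losses[alpha] = (sigma_alpha - sigma_{alpha+1}) / sigma_alpha``;
    a large loss after component alpha marks the elbow at which further
    constraints stop contributing appreciable structure.
    """

    singular_values: np.ndarray
    relative_losses: np.ndarray


def log_transform(matrix: AbundanceMatrix, pseudocount: float = 0.0) -> LogMatrix:
    """Elementwise L_it = ln(X_it + pseudocount).

    Use pseudocount 1 for integer count matrices containing zeros; with
    pseudocount 0 every abundance must be strictly positive.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    shifted = matrix.values + pseudocount
    if np.any(shifted <= 0):
        i = int(np.argwhere((shifted <= 0).any(axis=1))[0][0])
        raise ValueError(
            f"nonpositive abundance after pseudocount for entity {matrix.entity_ids[i]!r}"
        )
    return LogMatrix(
        list(matrix.entity_ids), list(matrix.condition_labels), np.log(shifted)
    )


def normalize_columns(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Scale each column to the mean column total (library-size style scaling).

    Off by default in the pipeline; offered because sequencing depth varies
    between samples while the decomposition acts on absolute log abundances.
    """
    totals = matrix.values.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("cannot normalize a column with nonpositive total")
    scaled = matrix.values * (totals.mean() / totals)
    return AbundanceMatrix(list(matrix.entity_ids), list(matrix.condition_labels), scaled)


def _apply_sign_convention(
    u: np.ndarray, v_rows: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Resolve SVD sign ambiguity in place; returns the flipped (U, Vt).

    Component 0 (baseline): flip so the weight column sums to >= 0, making the
    baseline weights predominantly positive as befits a state population.
    Components >= 1: flip so the potential is >= 0 at the first condition with
    a nonzero value (ties broken by later conditions).
    """
    u = u.copy()
    v_rows = v_rows.copy()
    for alpha in range(u.shape[1]):
        if alpha == 0:
            flip = u[:, 0].sum() < 0
        else:
            flip = False
            for t in range(v_rows.shape[1]):
                val = v_rows[alpha, t]
                if val != 0:
                    flip = val < 0
                    break
        if flip:
            u[:, alpha] = -u[:, alpha]
            v_rows[alpha] = -v_rows[alpha]
    return u, v_rows


def decompose(log_matrix: LogMatrix) -> SurprisalDecomposition:
    """Thin SVD of the log matrix with the deterministic sign convention.

    Keeps all min(entities, conditions) components; the caller truncates via
    ``max_constraint`` arguments downstream.
    """
    L = log_matrix.values
    if L.shape[0] < 2 or L.shape[1] < 2:
        raise ValueError("need at least 2 entities and 2 conditions")
    u, s, vt = np.linalg.svd(L, full_matrices=False)
    u, vt = _apply_sign_convention(u, vt)
    potentials = s[:, None] * vt
    return SurprisalDecomposition(
        weights=u,
        potentials=potentials,
        singular_values=s,
        entity_ids=list(log_matrix.entity_ids),
        condition_labels=list(log_matrix.condition_labels),
    )


def reconstruct(decomp: SurprisalDecomposition, max_constraint: int) -> LogMatrix:
    """Partial reconstruction using components 0..max_constraint."""
    decomp._check_component(max_constraint)
    k = max_constraint + 1
    values = decomp.weights[:, :k] @ decomp.potentials[:k, :]
    return LogMatrix(list(decomp.entity_ids), list(decomp.condition_labels), values)


def recovery_fraction(decomp: SurprisalDecomposition, max_constraint: int) -> float:
    """Fraction of total squared log-signal recovered by components 0..max_constraint.

    Equals sum of the leading squared singular values over the total, i.e.
    1 - ||L - L_hat||_F^2 / ||L||_F^2; nondecreasing in the cutoff and exactly
    1 at full rank. The zero matrix is defined as perfectly recovered.
    """
    decomp._check_component(max_constraint)
    s2 = decomp.singular_values**2
    total = s2.sum()
    if total == 0:
        return 1.0
    return float(s2[: max_constraint + 1].sum() / total)


def importance_spectrum(decomp: SurprisalDecomposition) -> ImportanceSpectrum:
    """Relative loss of importance between consecutive singular values."""
    s = decomp.singular_values
    losses = np.zeros(max(len(s) - 1, 0))
    for a in range(len(s) - 1):
        losses[a] = 0.0 if s[a] == 0 else (s[a] - s[a + 1]) / s[a]
    return ImportanceSpectrum(singular_values=s.copy(), relative_losses=losses)


def suggest_n_constraints(decomp: SurprisalDecomposition) -> int:
    """Elbow suggestion: the constraint index alpha >= 1 with the largest relative loss.

    The number of constraints to carry forward remains a user choice; this
    merely names the largest gap in the spectrum after the baseline.
    """
    spectrum = importance_spectrum(decomp)
    if len(spectrum.relative_losses) <= 1:
        return decomp.max_constraint
    return int(np.argmax(spectrum.relative_losses[1:]) + 1)


def free_energy(
    decomp: SurprisalDecomposition,
    matrix: AbundanceMatrix,
    constraint_indices: Sequence[int],
) -> FreeEnergyTable:
    """Free energy F_alpha(t) = -lambda_alpha(t) * sum_i X_i(t) G_ialpha.

    The baseline alpha = 0 is excluded: it defines the minimum-free-energy
    state the constraints deviate from, so the total-work sum starts at
    alpha = 1. ``matrix`` must be the same abundance matrix (same entity and
    condition ordering) that produced the decomposed log matrix.
    """
    indices = [int(a) for a in constraint_indices]
    if not indices:
        raise ValueError("no constraint indices given")
    for a in indices:
        if a == 0:
            raise ValueError("baseline component 0 is excluded from free energy")
        decomp._check_component(a)
    if matrix.entity_ids != decomp.entity_ids:
        raise ValueError("abundance matrix entities do not match decomposition")
    if matrix.condition_labels != decomp.condition_labels:
        raise ValueError("abundance matrix conditions do not match decomposition")
    per = np.empty((len(indices), len(decomp.condition_labels)))
    for row, a in enumerate(indices):
        # sum_i X_i(t) G_ialpha, then modulate by -lambda_alpha(t)
        weighted_abundance = matrix.values.T @ decomp.weights[:, a]
        per[row] = -decomp.potentials[a] * weighted_abundance
    return FreeEnergyTable(
        per_constraint=per,
        total=per.sum(axis=0),
        constraint_indices=indices,
        condition_labels=list(decomp.condition_labels),
    )
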