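"""Constrained transition-rate matrices for discrete-trait Markov models.

A :class:`QMatrix` is a continuous-time Markov generator over a finite
state alphabet, with the three classical constraint patterns: ER (all
off-diagonal rates equal), SYM (q_ij = q_ji) and ARD (all rates free).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np

__all__ = ["QMatrix"]

_PATTERNS = ("ER", "SYM", "ARD")


@dataclass(frozen=True)
class QMatrix:
    states: Tuple[str, ...]
    matrix: np.ndarray  # (k, k), rows sum to 0, off-diagonals >= 0
    pattern: str | None = None

    def __post_init__(self):
        M = np.asarray(self.matrix, dtype=float)
        k = len(self.states)
        if M.shape != (k, k):
            raise ValueError("matrix shape does not match state count")
        off = M.copy()
        np.fill_diagonal(off, 0.0)
        if (off < -1e-12).any():
            raise ValueError("off-diagonal rates must be non-negative")
        if np.abs(M.sum(axis=1)).max() > 1e-9 * max(1.0, np.abs(M).max()):
            raise ValueError("rows of a rate matrix must sum to zero")
        if self.pattern is not None and self.pattern not in _PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        object.__setattr__(self, "matrix", M)

    # ------------------------------------------------------------ builders

    @classmethod
    def er(cls, states: Sequence[str], rate: float) -> "QMatrix":
        k = len(states)
        M = np.full((k, k), float(rate))
        np.fill_diagonal(M, -(k - 1) * float(rate))
        return cls(tuple(states), M, "ER")

    @classmethod
    def sym(cls, states: Sequence[str], rates: Sequence[float]) -> "QMatrix":
        """``rates`` fills the upper triangle row-wise (k(k-1)/2 values)."""
        k = len(states)
        expected = k * (k - 1) // 2
        if len(rates) != expected:
            raise ValueError(f"SYM needs {expected} rates")
        M = np.zeros((k, k))
        it = iter(rates)
        for i in range(k):
            for j in range(i + 1, k):
                r = float(next(it))
                M[i, j] = M[j, i] = r
        np.fill_diagonal(M, -M.sum(axis=1))
        return cls(tuple(states), M, "SYM")

    @classmethod
    def ard(cls, states: Sequence[str], rates: Sequence[float]) -> "QMatrix":
        """``rates`` fills off-diagonals row-wise (k(k-1) values)."""
        k = len(states)
        expected = k * (k - 1)
        if len(rates) != expected:
            raise ValueError(f"ARD needs {expected} rates")
        M = np.zeros((k, k))
        it = iter(rates)
        for i in range(k):
            for j in range(k):
                if i != j:
                    M[i, j] = float(next(it))
        np.fill_diagonal(M, -M.sum(axis=1))
        return cls(tuple(states), M, "ARD")

    @classmethod
    def from_pattern(cls, states: Sequence[str], pattern: str,
                     rates: Sequence[float]) -> "QMatrix":
        if pattern == "ER":
            if len(rates) != 1:
                raise ValueError("ER needs exactly 1 rate")
            return cls.er(states, rates[0])
        if pattern == "SYM":
            return cls.sym(states, rates)
        if pattern == "ARD":
            return cls.ard(states, rates)
        raise ValueError(f"unknown pattern {pattern!r}")

    # ------------------------------------------------------------ helpers

    @property
    def k(self) -> int:
        return len(self.states)

    def n_free(self) -> int:
        return {"ER": 1, "SYM": self.k * (self.k - 1) // 2,
                "ARD": self.k * (self.k - 1)}.get(self.pattern or "ARD",
                                                  self.k * (self.k - 1))

    def state_index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise ValueError(f"state {state!r} not in alphabet {self.states}")

    def stationary(self) -> np.ndarray:
        """Stationary distribution (left null vector of Q, normalised)."""
        M = self.matrix
        k = self.k
        A = np.vstack([M.T, np.ones(k)])
        b = np.zeros(k + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        s = pi.sum()
        return pi / s if s > 0 else np.full(k, 1.0 / k)
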