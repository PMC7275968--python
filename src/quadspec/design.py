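"""Multilevel multifactor calibration design and the 18/7 calibration split.

The design places ``n_levels**2`` runs so that every factor visits each of
its levels exactly ``n_levels`` times and distinct factor columns are nearly
orthogonal.  Construction is cyclic: factor 1 follows a fixed generator
sequence in which every ordered pair of levels occurs exactly once around
the cycle (an Eulerian circuit on the complete digraph over the levels,
i.e. a generalized de Bruijn sequence of order 2); factor *j* is the same
sequence cyclically advanced by *j - 1* runs.  The ordered-pair property
makes the lag-1 column correlation exactly zero; the shipped 5-level
generator was additionally chosen with zero lag-2 and lag-3 autocorrelation,
so any four of its shifted columns are mutually orthogonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import ConcentrationMatrix

__all__ = [
    "DesignSpec",
    "multilevel_design",
    "scale_design",
    "split_calibration_validation",
    "DEFAULT_LEVELS",
    "DEFAULT_VALIDATION_ROWS",
]

# Fixed 5-level cyclic generator (coded levels 0..4).  Every ordered pair of
# levels occurs exactly once along the cycle; centered autocorrelations at
# lags 1-3 are exactly zero and |lag 4| = 0.04.
_GENERATOR_5 = (0, 0, 3, 1, 3, 0, 1, 4, 2, 3, 3, 4, 4, 1, 1, 0, 2, 1, 2, 0, 4, 3, 2, 2, 4)

#: per-analyte concentration levels (ug/mL) of the published four-drug design
DEFAULT_LEVELS: dict[str, list[float]] = {
    "AT": [5.0, 10.0, 15.0, 20.0, 25.0],
    "PR": [1.0, 3.5, 5.5, 8.0, 10.0],
    "HZ": [1.0, 3.5, 5.5, 8.0, 10.0],
    "LV": [1.0, 2.5, 4.0, 5.5, 7.0],
}

#: 1-based run indices held out as the external validation set
DEFAULT_VALIDATION_ROWS = frozenset({3, 4, 9, 15, 18, 20, 23})


@dataclass
class DesignSpec:
    """Parameters of a multilevel multifactor calibration design."""

    n_levels: int = 5
    n_factors: int = 4
    level_values: dict[str, list[float]] = field(default_factory=lambda: dict(DEFAULT_LEVELS))
    validation_rows: frozenset[int] | None = None

    def __post_init__(self) -> None:
        if self.validation_rows is None:
            self.validation_rows = (
                DEFAULT_VALIDATION_ROWS if (self.n_levels, self.n_factors) == (5, 4) else frozenset()
            )
        for name, levels in self.level_values.items():
            if len(levels) != self.n_levels:
                raise ValueError(
                    f"factor {name!r} has {len(levels)} level values, expected {self.n_levels}"
                )
        n_runs = self.n_levels**2
        bad = [r for r in self.validation_rows if not (1 <= r <= n_runs)]
        if bad:
            raise ValueError(f"validation rows {bad} outside 1..{n_runs}")


def _generator_sequence(n_levels: int) -> np.ndarray:
    if n_levels == 5:
        return np.array(_GENERATOR_5, dtype=int)
    # best-effort for other level counts: deterministic Eulerian circuit on
    # the complete digraph with loops (lag-1 orthogonality and balance hold;
    # higher lags are not optimized).
    arcs = {a: list(range(n_levels - 1, -1, -1)) for a in range(n_levels)}
    stack, circuit = [0], []
    while stack:
        v = stack[-1]
        if arcs[v]:
            stack.append(arcs[v].pop())
        else:
            circuit.append(stack.pop())
    seq = circuit[::-1][:-1]
    if len(seq) != n_levels**2:
        raise ValueError(f"no cyclic generator for {n_levels} levels")
    return np.array(seq, dtype=int)


def multilevel_design(spec: DesignSpec) -> ConcentrationMatrix:
    """Coded design: ``n_levels**2`` runs x ``n_factors`` columns, levels 0..n-1."""
    seq = _generator_sequence(spec.n_levels)
    n_runs = spec.n_levels**2
    cols = [np.roll(seq, -(j)) for j in range(spec.n_factors)]
    coded = np.column_stack(cols).astype(float)
    names = list(spec.level_values.keys())[: spec.n_factors]
    if len(names) < spec.n_factors:
        names += [f"F{j + 1}" for j in range(len(names), spec.n_factors)]
    samples = [f"mix{r:02d}" for r in range(1, n_runs + 1)]
    return ConcentrationMatrix(samples, names, coded)


def scale_design(
    coded: ConcentrationMatrix, level_values: dict[str, list[float]]
) -> ConcentrationMatrix:
    """Map coded levels {0..n-1} to physical concentrations, per factor.

    Level value lists must be given in increasing level order so the
    monotone level ordering is preserved.
    """
    values = coded.values.copy()
    for j, name in enumerate(coded.analytes):
        levels = level_values[name]
        codes = coded.values[:, j].astype(int)
        if np.any(codes < 0) or np.any(codes >= len(levels)):
            raise ValueError(f"coded levels for {name!r} outside 0..{len(levels) - 1}")
        values[:, j] = np.asarray(levels, dtype=float)[codes]
    return ConcentrationMatrix(list(coded.samples), list(coded.analytes), values)


def split_calibration_validation(
    design: ConcentrationMatrix, validation_rows: frozenset[int] | set[int] = DEFAULT_VALIDATION_ROWS
) -> tuple[ConcentrationMatrix, ConcentrationMatrix]:
    """Partition runs into calibration and external-validation sets.

    ``validation_rows`` are 1-based run indices; order within each part
    follows the original run order.
    """
    if not validation_rows:
        raise ValueError("validation_rows must be non-empty")
    n = len(design.samples)
    bad = [r for r in validation_rows if not (1 <= r <= n)]
    if bad:
        raise ValueError(f"validation rows {bad} outside 1..{n}")
    val_idx = [i for i in range(n) if (i + 1) in validation_rows]
    cal_idx = [i for i in range(n) if (i + 1) not in validation_rows]
    return design.subset(cal_idx), design.subset(val_idx)
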