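"""Taguchi-style range (polar-difference) analysis of an orthogonal experiment.

For a balanced design, K[l, f] is the mean response over the runs at level
``l`` of factor ``f`` and R[f] = max_l K[l, f] − min_l K[l, f].  A larger
range means the factor moves the response more across its levels, so sorting
factors by descending R gives a screening-level importance ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import N_LEVELS, DesignTable


class AlignmentError(ValueError):
    """Response vector does not line up with the design."""


@dataclass(frozen=True)
class RangeAnalysisResult:
    """Level-mean matrix K (levels × factors), range vector R and ranking.

    ``ranking`` lists factor indices by descending R; ties keep factor order.
    """

    factor_names: tuple[str, ...]
    K: np.ndarray
    R: np.ndarray
    ranking: tuple[int, ...]

    @property
    def ranked_names(self) -> tuple[str, ...]:
        return tuple(self.factor_names[f] for f in self.ranking)

    def to_frame(self) -> pd.DataFrame:
        """K/R report with 1-based level labels, mirroring the field's tables."""
        frame = pd.DataFrame(
            self.K,
            index=[f"K{l + 1}" for l in range(self.K.shape[0])],
            columns=list(self.factor_names),
        )
        frame.loc["R"] = self.R
        return frame


def _check_response(design: DesignTable, response) -> np.ndarray:
    y = np.asarray(response, dtype=float)
    if y.shape != (design.n_runs,):
        raise AlignmentError(
            f"response length {y.shape} does not match design with "
            f"{design.n_runs} runs"
        )
    if not np.all(np.isfinite(y)):
        raise AlignmentError("response contains non-finite values")
    return y


def level_means(design: DesignTable, response) -> np.ndarray:
    """K matrix: arithmetic mean of the response at each (level, factor) cell."""
    y = _check_response(design, response)
    n_factors = design.level_index.shape[1]
    K = np.empty((N_LEVELS, n_factors), dtype=float)
    for f in range(n_factors):
        for l in range(N_LEVELS):
            mask = design.level_index[:, f] == l
            if not mask.any():
                raise AlignmentError(
                    f"no runs at level {l + 1} of factor "
                    f"{design.factors[f].name!r}"
                )
            K[l, f] = y[mask].mean()
    return K


def compute_ranges(K: np.ndarray) -> tuple[np.ndarray, tuple[int, ...]]:
    """Range vector R = column max − column min, and the descending-R ranking."""
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] < 2:
        raise ValueError("K must be a matrix with at least two level rows")
    R = K.max(axis=0) - K.min(axis=0)
    # stable sort on -R keeps original factor order on ties
    ranking = tuple(int(f) for f in np.argsort(-R, kind="stable"))
    return R, ranking


def range_analysis(design: DesignTable, response) -> RangeAnalysisResult:
    """Full analysis: level means, ranges and factor-importance ranking."""
    K = level_means(design, response)
    R, ranking = compute_ranges(K)
    return RangeAnalysisResult(
        factor_names=tuple(f.name for f in design.factors),
        K=K,
        R=R,
        ranking=ranking,
    )
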