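"""Mixed-level orthogonal experiment design for the four-factor gardenia-blue study.

The experiment screens four reaction factors — temperature, geniposide dose,
glycine dose and reaction time — each at seven levels, using a strength-2
orthogonal array OA(49, 7^4, 2): every pair of factor columns contains every
ordered pair of levels exactly once, so main effects can be estimated from 49
runs instead of the 7^4 = 2401 of a full factorial.

The array is generated over GF(7): with block index ``a`` and within-block
index ``b`` running 0..6, the four columns are ``a``, ``b``, ``(a + b) mod 7``
and ``(2a + b) mod 7``.  Rows are emitted a-major then b, which is also the
run order of the packaged reference experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

N_LEVELS = 7
N_FACTORS = 4
N_RUNS = N_LEVELS * N_LEVELS

#: Canonical run-sheet column order (yield column optional on read).
RUN_SHEET_COLUMNS = ("run_id", "temperature_C", "geniposide", "glycine", "time_min")
YIELD_COLUMN = "yield_ugml"


class DesignError(ValueError):
    """Raised for invalid factor specifications or malformed design tables."""


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor: a name, a display unit and its 7 level values.

    Level order is preserved exactly as configured — it need not be sorted
    (the reference study's time column runs 5, 45, 20, 30, 60, 120, 180 min).
    """

    name: str
    unit: str
    levels: tuple[float, ...]

    def __post_init__(self) -> None:
        levels = tuple(float(v) for v in self.levels)
        if len(levels) != N_LEVELS:
            raise DesignError(
                f"factor {self.name!r} must have exactly {N_LEVELS} levels, "
                f"got {len(levels)}"
            )
        if not all(math.isfinite(v) for v in levels):
            raise DesignError(f"factor {self.name!r} has non-finite level values")
        if len(set(levels)) != N_LEVELS:
            raise DesignError(f"factor {self.name!r} has duplicate level values")
        object.__setattr__(self, "levels", levels)

    def value(self, index: int) -> float:
        """Physical value of a 0-based level index."""
        return map_levels(index, self)

    def index_of(self, value: float) -> int:
        """Inverse lookup: 0-based level index of a physical value."""
        for i, v in enumerate(self.levels):
            if math.isclose(v, float(value), rel_tol=0.0, abs_tol=1e-9):
                return i
        raise DesignError(f"{value!r} is not a level of factor {self.name!r}")


#: Factor layout of the reference 49-run study.  Dose units are carried as
#: printed in the source tables; the numeric level values are unambiguous.
REFERENCE_FACTORS: tuple[FactorSpec, ...] = (
    FactorSpec("temperature", "°C", (40, 50, 60, 70, 80, 90, 100)),
    FactorSpec("geniposide", "μg/mL", (240, 280, 320, 360, 400, 440, 480)),
    FactorSpec("glycine", "μg/mL", (2, 4, 6, 8, 10, 12, 14)),
    FactorSpec("time", "min", (5, 45, 20, 30, 60, 120, 180)),
)


@dataclass(frozen=True)
class DesignTable:
    """A realized design: level indices, mapped physical values and run ids.

    ``level_index`` is 0-based internally; user-facing reports are 1-based.
    """

    factors: tuple[FactorSpec, ...]
    level_index: np.ndarray  # (runs, factors), int
    run_id: np.ndarray  # (runs,), 1-based

    def __post_init__(self) -> None:
        idx = np.asarray(self.level_index, dtype=int)
        if idx.ndim != 2 or idx.shape[1] != len(self.factors):
            raise DesignError("level_index must be (runs, n_factors)")
        if idx.min() < 0 or idx.max() >= N_LEVELS:
            raise DesignError("level indices must lie in 0..6")
        run_id = np.asarray(self.run_id, dtype=int)
        if run_id.shape != (idx.shape[0],) or len(set(run_id.tolist())) != len(run_id):
            raise DesignError("run_id must be unique and aligned with rows")
        object.__setattr__(self, "level_index", idx)
        object.__setattr__(self, "run_id", run_id)

    @property
    def n_runs(self) -> int:
        return self.level_index.shape[0]

    @property
    def values(self) -> np.ndarray:
        """Physical factor values, one row per run."""
        out = np.empty(self.level_index.shape, dtype=float)
        for f, spec in enumerate(self.factors):
            out[:, f] = np.asarray(spec.levels)[self.level_index[:, f]]
        return out

    def to_frame(self, yields: np.ndarray | None = None) -> pd.DataFrame:
        """Run sheet as a DataFrame with the canonical column schema."""
        vals = self.values
        frame = pd.DataFrame(
            {
                "run_id": self.run_id,
                "temperature_C": vals[:, 0],
                "geniposide": vals[:, 1],
                "glycine": vals[:, 2],
                "time_min": vals[:, 3],
            }
        )
        if yields is not None:
            y = np.asarray(yields, dtype=float)
            if y.shape != (self.n_runs,):
                raise DesignError("yield vector not aligned with design rows")
            frame[YIELD_COLUMN] = y
        return frame


def map_levels(index: int, factor: FactorSpec) -> float:
    """Map a 0-based level index to the factor's physical value."""
    if not 0 <= index < N_LEVELS:
        raise DesignError(
            f"level index {index} out of range 0..{N_LEVELS - 1} "
            f"for factor {factor.name!r}"
        )
    return factor.levels[index]


def build_mixed_oa(factors: tuple[FactorSpec, ...] = REFERENCE_FACTORS) -> DesignTable:
    """Construct the strength-2 OA(49, 7^4) over GF(7).

    Columns are (a, b, a+b, 2a+b) mod 7 with rows a-major.  The generator
    coefficients (1, 1) and (2, 1) are distinct and non-zero mod 7, which
    guarantees strength 2 for every column pair.
    """
    factors = tuple(factors)
    if len(factors) != N_FACTORS:
        raise DesignError(f"expected {N_FACTORS} factors, got {len(factors)}")
    a, b = np.divmod(np.arange(N_RUNS), N_LEVELS)
    idx = np.column_stack([a, b, (a + b) % N_LEVELS, (2 * a + b) % N_LEVELS])
    return DesignTable(factors=factors, level_index=idx, run_id=np.arange(1, N_RUNS + 1))


def verify_strength2(
    design: DesignTable | np.ndarray,
) -> tuple[bool, tuple[int, int] | None]:
    """Exhaustively check the strength-2 property of a level-index matrix.

    Returns ``(True, None)`` iff every unordered column pair contains every
    ordered pair of levels (i, j) in {0..6}^2 exactly once; otherwise
    ``(False, (col_a, col_b))`` for the first violating pair.
    """
    idx = design.level_index if isinstance(design, DesignTable) else np.asarray(design)
    if idx.ndim != 2 or idx.shape[1] < 2:
        raise DesignError("need a 2-D table with at least two columns")
    for fa, fb in combinations(range(idx.shape[1]), 2):
        counts = np.zeros((N_LEVELS, N_LEVELS), dtype=int)
        np.add.at(counts, (idx[:, fa], idx[:, fb]), 1)
        if not np.all(counts == idx.shape[0] // (N_LEVELS * N_LEVELS)):
            return False, (fa, fb)
    return True, None
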