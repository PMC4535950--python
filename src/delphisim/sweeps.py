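"""Monte-Carlo sweeps of Delphi survey characteristics.

One survey characteristic — number of questions, panel size, or the Group
Conformity Index — is varied across a grid while the other two stay at the
baseline (12 questions, 20 experts, GCI 0.5).  Each grid condition is
simulated many times (default 1000 replicates); the median of the study-wide
value over replicates represents the condition.  An index's *dependency* on
the swept characteristic is the spread of those medians:

    dependency = max over grid of median  -  min over grid of median

For the IQR, whose natural range is the scale length rather than [0, 1],
the dependency is normalised by ``scale_max - 1`` (9 on a 1-10 scale) so all
nine dependencies share the 0-1 reading: 0 = the characteristic does not
move the index at all, 1 = it moves it across its whole range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .indices import ALL_INDICES
from .simulate import SimulationConfig, run_study

logger = logging.getLogger(__name__)

#: Characteristics that can be swept, with the stable integer codes used to
#: derive per-condition random streams.
SWEEPABLE = ("n_items", "n_experts", "gci")
_PARAM_CODE = {"n_items": 1, "n_experts": 2, "gci": 3}

#: Grids of the three survey characteristics: every integer question count
#: 6..40, every integer panel size 6..50, GCI 0.0..1.0 in steps of 0.1.
DEFAULT_GRIDS: dict[str, tuple] = {
    "n_items": tuple(range(6, 41)),
    "n_experts": tuple(range(6, 51)),
    "gci": tuple(round(0.1 * g, 1) for g in range(11)),
}


def _condition_key(parameter: str, value: float) -> int:
    """Stable integer identifying one grid condition (keyed by value, not
    position, so reordering the grid cannot change any replicate stream)."""
    return int(round(float(value) * 1000))


@dataclass(frozen=True)
class SweepSpec:
    """One single-characteristic sweep.

    ``grid=None`` selects the default grid of the swept parameter.  The
    baseline supplies the two held-fixed characteristics (and the scale,
    clustering and round count shared by every condition).
    """

    parameter: str
    grid: tuple | None = None
    baseline: SimulationConfig = field(default_factory=SimulationConfig)
    replicates: int = 1000
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.parameter not in SWEEPABLE:
            raise ValueError(f"parameter must be one of {SWEEPABLE}")
        if self.grid is not None and len(self.grid) == 0:
            raise ValueError("grid must be non-empty")
        if self.replicates < 1:
            raise ValueError("replicates must be at least 1")

    @property
    def resolved_grid(self) -> tuple:
        return DEFAULT_GRIDS[self.parameter] if self.grid is None else tuple(self.grid)


@dataclass(frozen=True)
class DependencyTable:
    """Per-condition medians and each index's dependency for one sweep.

    ``medians`` has one row per index and one column per grid value.
    ``dependency`` is max median minus min median per index (IQR divided by
    ``scale_max - 1``), sorted descending; ``raw_dependency`` keeps the
    un-normalised spreads.
    """

    parameter: str
    grid: tuple
    medians: pd.DataFrame
    dependency: pd.Series
    raw_dependency: pd.Series
    replicates: int
    master_seed: int

    @property
    def ranking(self) -> list[str]:
        """Index names ordered by dependency, largest first."""
        return list(self.dependency.index)

    def to_frame(self) -> pd.DataFrame:
        """The rank-order table: one row per index with dependency and rank."""
        return pd.DataFrame({
            "index": self.dependency.index,
            "dependency": np.round(self.dependency.to_numpy(), 3),
            "rank": np.arange(1, len(self.dependency) + 1),
        })

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "grid": list(self.grid),
            "replicates": self.replicates,
            "master_seed": self.master_seed,
            "medians": {k: [float(x) for x in row]
                        for k, row in self.medians.iterrows()},
            "dependency": {k: float(v) for k, v in self.dependency.items()},
            "raw_dependency": {k: float(v) for k, v in self.raw_dependency.items()},
            "ranking": self.ranking,
        }


def run_condition(config: SimulationConfig, replicates: int,
                  stream: np.random.SeedSequence) -> dict[str, float]:
    """Median study-wide value of each index under one survey condition.

    Runs `replicates` independent studies, each on its own child stream of
    `stream` (no stream is ever shared between replicates), and takes the
    median over replicates of each index's study-wide value.  An even
    replicate count averages the two central order statistics.
    """
    values = np.empty((replicates, len(ALL_INDICES)))
    for rep, child in enumerate(stream.spawn(replicates)):
        result = run_study(config, np.random.default_rng(child))
        for j, name in enumerate(ALL_INDICES):
            values[rep, j] = result.index_reports[name].study_wide
    med = np.median(values, axis=0)
    return {name: float(med[j]) for j, name in enumerate(ALL_INDICES)}


def run_sweep(spec: SweepSpec) -> DependencyTable:
    """Sweep one characteristic over its grid and tabulate dependencies.

    Each grid condition gets its own random stream derived from
    ``(master_seed, parameter, condition value)``, so results are
    reproducible and independent of grid ordering.
    """
    grid = spec.resolved_grid
    code = _PARAM_CODE[spec.parameter]
    medians: dict[float, dict[str, float]] = {}
    for value in grid:
        config = replace(spec.baseline, **{spec.parameter: value})
        stream = np.random.SeedSequence(
            [spec.master_seed, code, _condition_key(spec.parameter, value)])
        medians[value] = run_condition(config, spec.replicates, stream)
        logger.info("sweep %s=%s done (%d replicates)", spec.parameter, value,
                    spec.replicates)
    table = pd.DataFrame(medians).reindex(list(ALL_INDICES))
    raw = table.max(axis=1) - table.min(axis=1)
    dep = raw.copy()
    dep.loc["IQR"] = raw.loc["IQR"] / (spec.baseline.scale_max - 1)
    dep = dep.sort_values(ascending=False, kind="stable")
    return DependencyTable(spec.parameter, tuple(grid), table, dep,
                           raw.loc[dep.index], spec.replicates, spec.master_seed)


def reproduce_tables(master_seed: int, replicates: int = 1000,
                     baseline: SimulationConfig | None = None
                     ) -> dict[str, DependencyTable]:
    """The three rank-order dependency tables, one per survey characteristic.

    Returns tables keyed ``"n_items"`` (question-count sweep 6-40),
    ``"n_experts"`` (panel-size sweep 6-50) and ``"gci"`` (conformity sweep
    0.0-1.0), each at `replicates` studies per grid condition.
    """
    baseline = baseline or SimulationConfig()
    out = {}
    for parameter in SWEEPABLE:
        spec = SweepSpec(parameter, baseline=baseline, replicates=replicates,
                         master_seed=master_seed)
        out[parameter] = run_sweep(spec)
    return out
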