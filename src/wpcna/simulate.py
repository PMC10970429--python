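"""Synthetic phosphoproteomic studies with planted ground truth.

The generator emulates the design the pipeline targets: ~20 animals in
four genotype x exposure groups (tau-transgenic rTg4510 vs non-carrier,
blast vs sham), a few thousand peptides of which a minority is organized
into correlated modules, one module whose latent factor drives the
discrimination-learning index, missing intensities, and CognitionWall
entry logs whose recomputed learning index matches the simulated one.

Each planted module m follows a single-factor Gaussian model

    x_i = baseline_i + noise_sd * (sqrt(rho) * f_m + sqrt(1 - rho) * eps_i)

with a shared latent factor ``f_m ~ N(0, 1)`` over animals, so the
expected pairwise correlation within the module is rho.  Background
peptides are independent noise.  The learning index is
``trait_cor * f_m + sqrt(1 - trait_cor^2) * noise`` standardized and
affine-mapped to mean 0.4, SD 0.3 — the plausible range for CognitionWall
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import DailyEntryCounts

__all__ = [
    "SimConfig",
    "SimulatedStudy",
    "GROUP_NAMES",
    "simulate_module_structure",
    "simulate_learning",
    "simulate_entry_logs",
    "simulate_study",
]

GROUP_NAMES = ("rTg4510-blast", "rTg4510-sham", "nc-blast", "nc-sham")

_BASELINE_MEAN = 20.0  # typical log2 MS2 intensity
_BASELINE_SD = 2.0


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic study.

    Defaults mirror the target design: 20 animals in groups of
    (5, 5, 6, 4), 1000 peptides with three planted modules at
    within-module correlation 0.6, the first module's factor correlated
    0.7 with the learning index, and 2% missing cells.
    """

    n_animals: int = 20
    group_sizes: tuple[int, int, int, int] = (5, 5, 6, 4)
    n_peptides: int = 1000
    module_sizes: tuple[int, ...] = (120, 60, 40)
    within_module_cor: float | tuple[float, ...] = 0.6
    trait_module_index: int = 0
    trait_cor: float = 0.7
    noise_sd: float = 1.0
    missing_rate: float = 0.02
    index_mean: float = 0.4
    index_sd: float = 0.3
    total_entries_per_day: int = 200
    seed: int = 0

    def module_correlations(self) -> tuple[float, ...]:
        rho = self.within_module_cor
        if np.isscalar(rho):
            return tuple(float(rho) for _ in self.module_sizes)
        rho = tuple(float(r) for r in rho)  # type: ignore[union-attr]
        if len(rho) != len(self.module_sizes):
            raise ValueError("one within_module_cor per module required")
        return rho

    def validate(self) -> None:
        if sum(self.group_sizes) != self.n_animals:
            raise ValueError(
                f"group sizes {self.group_sizes} must sum to {self.n_animals}"
            )
        if sum(self.module_sizes) > self.n_peptides:
            raise ValueError("module_sizes exceed n_peptides")
        for rho in self.module_correlations():
            if not 0.0 <= rho <= 1.0:
                raise ValueError("within_module_cor must be in [0, 1]")
        if not -1.0 <= self.trait_cor <= 1.0:
            raise ValueError("trait_cor must be in [-1, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.module_sizes and not (
            0 <= self.trait_module_index < len(self.module_sizes)
        ):
            raise ValueError("trait_module_index out of range")


@dataclass
class SimulatedStudy:
    """A generated study plus its ground truth."""

    intensities: pd.DataFrame  # peptides x animals, log2, NaN = missing
    metadata: pd.DataFrame  # animal_id-indexed: genotype, exposure, group
    entry_logs: pd.DataFrame  # animal_id, day, CE, IE, TE
    truth_modules: pd.Series  # peptide_id -> planted label ("none" = background)
    factors: pd.DataFrame  # module label x animal latent factors
    true_index: pd.Series  # animal_id -> simulated learning index
    config: SimConfig = field(repr=False, default=None)  # type: ignore[assignment]


def _animal_metadata(config: SimConfig) -> pd.DataFrame:
    rows = []
    for group, size in zip(GROUP_NAMES, config.group_sizes):
        genotype, exposure = group.rsplit("-", 1)
        for i in range(size):
            rows.append(
                {
                    "animal_id": f"{group}-{i + 1}",
                    "genotype": genotype,
                    "exposure": exposure,
                    "group": group,
                }
            )
    return pd.DataFrame(rows).set_index("animal_id")


def simulate_module_structure(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Draw the intensity matrix with planted correlated modules.

    Returns (intensities, truth labels, latent factors).  Missing cells
    are injected completely at random at ``missing_rate``, never blanking
    an entire row or column.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, p = config.n_animals, config.n_peptides
    animals = _animal_metadata(config).index
    rhos = config.module_correlations()

    labels = np.array(["none"] * p, dtype=object)
    module_names = [f"m{i + 1}" for i in range(len(config.module_sizes))]
    factors = rng.standard_normal((len(config.module_sizes), n))

    X = rng.standard_normal((p, n))  # iid noise for everyone
    start = 0
    for m, (size, rho) in enumerate(zip(config.module_sizes, rhos)):
        block = slice(start, start + size)
        labels[block] = module_names[m]
        X[block] = np.sqrt(rho) * factors[m] + np.sqrt(1.0 - rho) * X[block]
        start += size

    baselines = _BASELINE_MEAN + _BASELINE_SD * rng.standard_normal(p)
    X = baselines[:, None] + config.noise_sd * X

    peptide_ids = [f"pep{i + 1:05d}" for i in range(p)]
    intensities = pd.DataFrame(X, index=peptide_ids, columns=animals)
    intensities.index.name = "peptide_id"

    if config.missing_rate > 0:
        mask = rng.random((p, n)) < config.missing_rate
        # never blank a whole row or column
        for i in np.flatnonzero(mask.all(axis=1)):
            mask[i, rng.integers(n)] = False
        for j in np.flatnonzero(mask.all(axis=0)):
            mask[rng.integers(p), j] = False
        intensities = intensities.mask(mask)

    truth = pd.Series(labels, index=peptide_ids, name="module")
    truth.index.name = "peptide_id"
    factor_table = pd.DataFrame(factors, index=module_names, columns=animals)
    return intensities, truth, factor_table


def simulate_learning(
    factors: pd.DataFrame,
    trait_module_index: int,
    trait_cor: float,
    seed: int | np.random.Generator,
    index_mean: float = 0.4,
    index_sd: float = 0.3,
) -> pd.Series:
    """Simulate a learning index correlated with one module's factor.

    The raw index is ``trait_cor * z(f) + sqrt(1 - trait_cor^2) * noise``,
    then standardized and affine-mapped to (index_mean, index_sd).
    """
    if not -1.0 <= trait_cor <= 1.0:
        raise ValueError("trait_cor must be in [-1, 1]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    f = factors.iloc[trait_module_index].to_numpy(dtype=float)
    z = (f - f.mean()) / f.std()
    raw = trait_cor * z + np.sqrt(1.0 - trait_cor**2) * rng.standard_normal(len(z))
    if raw.std() > 0:
        raw = (raw - raw.mean()) / raw.std()
    index = index_mean + index_sd * raw
    return pd.Series(index, index=factors.columns, name="index")


def simulate_entry_logs(
    target_index_day1: float,
    target_index_day2: float,
    total_entries_per_day: int,
    animal_id: str = "animal",
) -> tuple[DailyEntryCounts, DailyEntryCounts]:
    """Build daily entry counts achieving given per-day learning fractions.

    Inverts the per-day fraction ``(CE - IE)/TE = target``:
    ``CE = round(TE * (1 + target) / 2)``, ``IE = TE - CE``.  Recomputing
    the learning index on the output reproduces
    ``target_index_day2 - target_index_day1`` up to rounding (at most
    1/TE per day).
    """
    if total_entries_per_day < 1:
        raise ValueError("total_entries_per_day must be >= 1")
    days = []
    for day, target in ((1, target_index_day1), (2, target_index_day2)):
        if not -1.0 <= target <= 1.0:
            raise ValueError(f"per-day target {target} outside [-1, 1]")
        TE = int(total_entries_per_day)
        CE = int(round(TE * (1.0 + target) / 2.0))
        days.append(DailyEntryCounts(animal_id, day, CE, TE - CE, TE))
    return days[0], days[1]


def simulate_study(config: SimConfig | None = None, **overrides) -> SimulatedStudy:
    """Generate a complete study: intensities, metadata, entry logs, truth.

    Per-animal entry logs are constructed so that the recomputed learning
    index equals the simulated one up to count rounding: day-1 fraction is
    ``-index/2`` and day-2 fraction ``+index/2``.
    """
    if config is None:
        config = SimConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a SimConfig or keyword overrides, not both")
    config.validate()
    rng = np.random.default_rng(config.seed)

    metadata = _animal_metadata(config)
    intensities, truth, factors = simulate_module_structure(config, rng)
    if len(config.module_sizes) > 0:
        true_index = simulate_learning(
            factors,
            config.trait_module_index,
            config.trait_cor,
            rng,
            config.index_mean,
            config.index_sd,
        )
    else:
        true_index = pd.Series(
            config.index_mean + config.index_sd * rng.standard_normal(config.n_animals),
            index=metadata.index,
            name="index",
        )

    rows = []
    for animal, idx in true_index.items():
        half = float(np.clip(idx, -2.0, 2.0)) / 2.0
        d1, d2 = simulate_entry_logs(
            -half, half, config.total_entries_per_day, str(animal)
        )
        for d in (d1, d2):
            rows.append(
                {"animal_id": d.animal_id, "day": d.day, "CE": d.CE, "IE": d.IE, "TE": d.TE}
            )
    entry_logs = pd.DataFrame(rows)

    return SimulatedStudy(
        intensities=intensities,
        metadata=metadata,
        entry_logs=entry_logs,
        truth_modules=truth,
        factors=factors,
        true_index=true_index,
        config=config,
    )
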