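"""Hierarchical aggregation, transformation and resampling inference.

Spine-level measurements are pseudoreplicated — spines nest in dendrites,
slices and animals — so group summaries average within animal first and
inference permutes treatment labels at the level at which treatment was
actually assigned (slices within animal, or whole animals).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ABETA40_MASS_G_PER_MOL",
    "ABETA42_MASS_G_PER_MOL",
    "animal_averages",
    "tukey_ladder_transform",
    "PermutationResult",
    "hierarchical_permutation_test",
    "pg_per_ml_to_pM",
]

#: Average isotopic molar masses of the two main amyloid-beta species.
ABETA40_MASS_G_PER_MOL = 4329.8
ABETA42_MASS_G_PER_MOL = 4514.1


def animal_averages(
    df: pd.DataFrame,
    value_col: str,
    group_cols: list[str] | tuple[str, ...] = (),
    animal_col: str = "animal",
) -> pd.DataFrame:
    """Two-stage group summary: spine values are averaged within animal,
    then animal means are averaged (unweighted) within each group.

    Infinite values (e.g. ΔHz/Hz of spines silent at PRE) are excluded
    from the means and counted in ``n_inf_excluded``.
    """
    group_cols = list(group_cols)
    for col in group_cols + [animal_col, value_col]:
        if col not in df.columns:
            raise KeyError(f"missing column {col!r}")
    work = df[group_cols + [animal_col, value_col]].copy()
    finite = np.isfinite(work[value_col].astype(float))
    n_inf = (~finite & work[value_col].notna()).astype(int)
    work["_n_inf"] = n_inf
    work = work.assign(**{value_col: work[value_col].where(finite)})

    keys = group_cols + [animal_col] if group_cols else [animal_col]
    per_animal = work.groupby(keys, sort=True, dropna=False).agg(
        animal_mean=(value_col, "mean"),
        n_spines=(value_col, "count"),
        n_inf_excluded=("_n_inf", "sum"),
    ).reset_index()
    if not group_cols:
        per_animal["_all"] = 0
        group_cols = ["_all"]
    out = per_animal.groupby(group_cols, sort=True, dropna=False).agg(
        mean=("animal_mean", "mean"),
        n_animals=("animal_mean", "count"),
        n_spines=("n_spines", "sum"),
        n_inf_excluded=("n_inf_excluded", "sum"),
    ).reset_index()
    return out.drop(columns=["_all"], errors="ignore")


_LAMBDA_GRID = np.arange(-2.0, 2.0 + 1e-9, 0.25)


def tukey_ladder_transform(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Tukey ladder-of-powers transform towards normality.

    The sample is shifted to strict positivity if needed, then the power
    λ is chosen on the grid −2 … 2 (step 0.25) maximising the
    Shapiro–Wilk W of the transformed sample.  Negative powers are
    negated so the transform is increasing (rank-preserving) for every λ.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3 or np.ptp(x) == 0:
        raise ValueError("need at least 3 distinct finite values")
    if x.min() <= 0:
        x = x - x.min() + 0.01 * np.ptp(x)

    def apply(lam: float, v: np.ndarray) -> np.ndarray:
        if lam == 0:
            return np.log(v)
        y = v ** lam
        return y if lam > 0 else -y

    best_lam, best_w = 1.0, -np.inf
    for lam in _LAMBDA_GRID:
        y = apply(lam, x)
        if not np.all(np.isfinite(y)) or np.ptp(y) == 0:
            continue
        w = sps.shapiro(y[:5000]).statistic
        if w > best_w:
            best_w, best_lam = w, lam
    return apply(best_lam, x), float(best_lam)


@dataclass
class PermutationResult:
    """Observed statistic and permutation p-value of a two-arm contrast."""

    observed: float
    p_value: float
    arms: tuple
    n_perm: int
    exchange_unit: str


def hierarchical_permutation_test(
    df: pd.DataFrame,
    value_col: str,
    group_col: str,
    animal_col: str = "animal",
    unit_col: str = "slice",
    exchange: str = "slice",
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> PermutationResult:
    """Permutation test respecting the nested design.

    The statistic is the difference of animal-averaged means between the
    two levels of ``group_col``.  Labels are permuted at the exchangeable-
    unit level: ``exchange="slice"`` shuffles slice labels within each
    animal (treatment assigned to slices, within-animal design);
    ``exchange="animal"`` shuffles whole animals.  The test refuses
    designs where the factor varies below the exchange unit.

    p = (1 + #{|stat_perm| ≥ |stat_obs|}) / (1 + n_perm).
    """
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    arms = tuple(sorted(pd.unique(df[group_col])))
    if len(arms) != 2:
        raise ValueError(f"group_col must have exactly 2 levels, got {arms}")
    vals = df[value_col].astype(float).to_numpy()
    finite = np.isfinite(vals)
    df = df.loc[finite]
    vals = vals[finite]

    if exchange == "animal":
        unit_keys = [animal_col]
    elif exchange == "slice":
        unit_keys = [animal_col, unit_col]
    else:
        raise ValueError("exchange must be 'slice' or 'animal'")
    per_unit_levels = df.groupby(unit_keys)[group_col].nunique()
    if (per_unit_levels > 1).any():
        raise ValueError(
            f"{group_col} varies within an exchange unit ({exchange}); "
            "permuting there would break exchangeability"
        )
    units = df.groupby(unit_keys).agg(
        _sum=(value_col, lambda v: np.sum(v)),
        _cnt=(value_col, "size"),
        _grp=(group_col, "first"),
    ).reset_index()
    labels = (units["_grp"] == arms[1]).to_numpy()
    for arm_flag in (True, False):
        if (labels == arm_flag).sum() < 2:
            raise ValueError("need at least 2 exchange units per arm")
    sums = units["_sum"].to_numpy(float)
    cnts = units["_cnt"].to_numpy(float)
    if exchange == "slice":
        animal_of_unit = units[animal_col].to_numpy()
    else:
        animal_of_unit = units[animal_col].to_numpy()
    animals = pd.unique(animal_of_unit)

    # permuted label matrix: shuffle within animal blocks (or globally)
    lab_mat = np.tile(labels, (n_perm, 1))
    if exchange == "slice":
        for a in animals:
            block = np.flatnonzero(animal_of_unit == a)
            lab_mat[:, block] = rng.permuted(lab_mat[:, block], axis=1)
    else:
        lab_mat = rng.permuted(lab_mat, axis=1)

    def stats_for(lmat: np.ndarray) -> np.ndarray:
        # animal-arm means -> arm means averaged over contributing animals
        npr = lmat.shape[0]
        arm_means = np.zeros((2, npr))
        for k, flag in enumerate((False, True)):
            num = np.zeros((npr, animals.size))
            den = np.zeros((npr, animals.size))
            for ai, a in enumerate(animals):
                block = animal_of_unit == a
                m = (lmat[:, block] == flag)
                num[:, ai] = m @ sums[block]
                den[:, ai] = m @ cnts[block]
            with np.errstate(invalid="ignore", divide="ignore"):
                am = num / den
            arm_means[k] = np.nanmean(am, axis=1)
        return arm_means[1] - arm_means[0]

    observed = float(stats_for(labels[None, :])[0])
    perm = stats_for(lab_mat)
    p = (1.0 + np.sum(np.abs(perm) >= np.abs(observed) - 1e-12)) / (1.0 + n_perm)
    return PermutationResult(observed, float(p), arms, n_perm, exchange)


def pg_per_ml_to_pM(mass_conc_pg_ml: float, molar_mass_g_mol: float) -> float:
    """Convert a mass concentration to picomolar.

    pg/mL equals ng/L, so dividing by the molar mass (g/mol) gives
    nmol/L; a factor of 1000 lands on pmol/L.
    """
    if mass_conc_pg_ml <= 0 or molar_mass_g_mol <= 0:
        raise ValueError("concentration and molar mass must be positive")
    return 1000.0 * mass_conc_pg_ml / molar_mass_g_mol
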