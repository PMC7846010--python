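"""Scalar quantifications: ROI fluorescence, labeling efficiency, synergism.

* :func:`roi_mean_intensity` — mean fluorescence (arbitrary units) of a
  square ROI, the per-cell internalization proxy.
* :func:`kruskal_wallis_with_posthoc` — tie-corrected Kruskal-Wallis H
  over condition groups with Dunn pairwise post-hoc tests
  (Holm-adjusted p-values).
* :func:`labeling_efficiency` — degree of labeling (moles of conjugated
  dye per mole of protein) from peak absorbance, the dye's molar
  extinction coefficient, and the protein concentration.
* :func:`tabashnik_sf` — synergism factor of a two-component mixture:
  the additive-expectation (harmonic) mixture LC50 divided by the
  observed mixture LC50; SF > 1 indicates synergism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from nanolayers.containers import GeometryError, InvalidParameterError

__all__ = [
    "LabelingMeasurement",
    "Lc50Set",
    "KruskalDunnResult",
    "roi_mean_intensity",
    "kruskal_dunn",
    "kruskal_wallis_with_posthoc",
    "labeling_efficiency",
    "tabashnik_sf",
]

# Alexa Fluor NHS-ester extinction coefficients (M^-1 cm^-1 at the
# absorbance peak), for convenience when computing degrees of labeling.
EXTINCTION_COEFFICIENTS = {"alexa546": 203_000.0, "alexa647": 270_000.0}


@dataclass
class LabelingMeasurement:
    """Inputs of a degree-of-labeling determination."""

    absorbance_peak: float
    extinction_coefficient: float  # M^-1 cm^-1
    molecular_weight: float        # g/mol
    protein_concentration: float   # mg/ml

    def __post_init__(self) -> None:
        for name in ("absorbance_peak", "extinction_coefficient",
                     "molecular_weight", "protein_concentration"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be > 0")


@dataclass
class Lc50Set:
    """LC50 values (ng/ml) of two components and their observed mixture."""

    lc50_a: float
    lc50_b: float
    lc50_mix_observed: float
    mixture_ratio: float = 0.5  # fraction of component a in the mixture
    ci_a: tuple[float, float] | None = None
    ci_b: tuple[float, float] | None = None
    ci_mix: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if min(self.lc50_a, self.lc50_b, self.lc50_mix_observed) <= 0:
            raise InvalidParameterError("all LC50 values must be > 0")
        if not (0.0 < self.mixture_ratio < 1.0):
            raise InvalidParameterError("mixture_ratio must be in (0, 1)")


@dataclass
class KruskalDunnResult:
    h: float
    p: float
    pairwise: pd.DataFrame  # columns: group_1, group_2, z, p_raw, p_adj, reject
    group_sizes: dict[str, int]


def roi_mean_intensity(image: np.ndarray, row: int, col: int,
                       size: int) -> float:
    """Arithmetic mean pixel value of the ``size x size`` square at (row, col)."""
    image = np.asarray(image)
    if row < 0 or col < 0 or row + size > image.shape[0] or col + size > image.shape[1]:
        raise GeometryError("ROI square falls outside the image")
    return float(image[row:row + size, col:col + size].mean())


def kruskal_dunn(groups: Mapping[str, Sequence[float]],
                 alpha: float = 0.05) -> KruskalDunnResult:
    """Tie-corrected Kruskal-Wallis H with Dunn post-hoc (Holm adjustment).

    Dunn's z statistic for groups i, j compares mean ranks over the
    pooled sample: ``z = (Rbar_i - Rbar_j) / sqrt(S * (1/n_i + 1/n_j))``
    with ``S = (N(N+1)/12) - T / (12 (N-1))`` where ``T = sum(t^3 - t)``
    over tie groups.
    """
    labels = list(groups)
    data = [np.asarray(groups[k], dtype=float) for k in labels]
    sizes = {k: len(v) for k, v in zip(labels, data)}
    pooled = np.concatenate(data)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)

    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*data)

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts))
    s2 = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    mean_ranks, idx = {}, 0
    for k, v in zip(labels, data):
        mean_ranks[k] = ranks[idx:idx + len(v)].mean()
        idx += len(v)

    rows = []
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            ka, kb = labels[a], labels[b]
            se = np.sqrt(s2 * (1.0 / sizes[ka] + 1.0 / sizes[kb]))
            z = (mean_ranks[ka] - mean_ranks[kb]) / se if se > 0 else 0.0
            p_raw = 2.0 * stats.norm.sf(abs(z))
            rows.append((ka, kb, z, p_raw))
    pair = pd.DataFrame(rows, columns=["group_1", "group_2", "z", "p_raw"])
    if len(pair):
        reject, p_adj, _, _ = multipletests(pair["p_raw"], alpha=alpha,
                                            method="holm")
        pair["p_adj"] = p_adj
        pair["reject"] = reject
    return KruskalDunnResult(h=float(h), p=float(p), pairwise=pair,
                             group_sizes=sizes)


def kruskal_wallis_with_posthoc(table: pd.DataFrame,
                                condition_col: str = "condition",
                                value_col: str = "mean_intensity",
                                min_per_group: int = 3,
                                alpha: float = 0.05) -> KruskalDunnResult:
    """Group an ROI intensity table by condition and run Kruskal-Wallis + Dunn.

    Conditions with fewer than ``min_per_group`` cells are excluded with
    a warning.
    """
    groups: dict[str, np.ndarray] = {}
    for cond, sub in table.groupby(condition_col, sort=False):
        vals = sub[value_col].to_numpy(dtype=float)
        if len(vals) < min_per_group:
            warnings.warn(
                f"condition {cond!r} has only {len(vals)} cells "
                f"(< {min_per_group}); excluded", stacklevel=2)
            continue
        groups[str(cond)] = vals
    if len(groups) < 2:
        raise InvalidParameterError("need >= 2 usable conditions")
    return kruskal_dunn(groups, alpha=alpha)


def labeling_efficiency(m: LabelingMeasurement) -> float:
    """Degree of labeling: moles of dye per mole of protein.

    Molar dye concentration is ``A / epsilon`` (Beer-Lambert, 1 cm
    path); molar protein concentration is ``(mg/ml) / MW`` since
    mg/ml = g/L.  The DOL is their ratio.
    """
    dye_molar = m.absorbance_peak / m.extinction_coefficient
    protein_molar = m.protein_concentration / m.molecular_weight
    return dye_molar / protein_molar


def tabashnik_sf(s: Lc50Set) -> tuple[float, float]:
    """Additive-expectation mixture LC50 and synergism factor.

    Under simple additivity, a mixture with mass fraction ``rho`` of
    component a has theoretical
    ``LC50 = [rho / LC50_a + (1 - rho) / LC50_b]^{-1}`` (harmonic
    mixing).  The synergism factor divides this theoretical toxicity by
    the observed mixture LC50.
    """
    rho = s.mixture_ratio
    theoretical = 1.0 / (rho / s.lc50_a + (1.0 - rho) / s.lc50_b)
    return theoretical, theoretical / s.lc50_mix_observed
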