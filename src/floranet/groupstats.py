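"""Stage-wise statistics for phytohormone and sugar measurements.

Concentration panels (by default 12 phytohormones measured by HPLC-MS/MS and
4 sugar assays) are compared across developmental stages with one-way ANOVA
followed by Duncan's multiple range test at p < 0.05, summarized as a compact
letter display. The module also provides the per-analyte log2 fold changes
that feed compound nodes of the co-expression network, and linear
calibration curves (concentration vs peak area) for the assay standards.

Duncan's test compares the ordered group means stepwise. A span of ``p``
adjacent ordered means is declared heterogeneous when its range exceeds the
critical range

    R_p = q*(alpha_p, p, df_e) * sqrt(MSE / r),

where ``q*`` is the studentized-range quantile at the protection level
``alpha_p = 1 - (1 - alpha)^(p-1)``, MSE and ``df_e`` come from the ANOVA,
and ``r`` is the (harmonic mean) replicate count. A range contained in a
homogeneous wider range is never declared heterogeneous.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .design import SampleDesign
from .diffexpr import Contrast

KINDS = ("hormone", "sugar")

DEFAULT_HORMONES: tuple[str, ...] = (
    "SA", "JA", "JA-ILE", "OPDA", "ABA", "GA1", "GA3", "GA4", "IAA", "TZR", "ZT", "ACC",
)
DEFAULT_SUGARS: tuple[str, ...] = ("total_sugar", "soluble_sugar", "trehalose", "sucrose")


class GroupStatsError(ValueError):
    pass


@dataclass
class CompoundTable:
    """Analyte concentrations (analytes x samples) with an analyte kind.

    ``values`` may contain NaN (assay dropouts); statistics drop them
    pairwise and refuse (analyte, stage) cells with fewer than 2 values.
    """

    values: pd.DataFrame
    kinds: pd.Series  # analyte -> 'hormone' | 'sugar'

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise GroupStatsError(f"duplicate analyte id(s): {dupes}")
        if not (self.values.index == self.kinds.index).all():
            raise GroupStatsError("kind vector not aligned with analyte rows")
        unknown = set(self.kinds) - set(KINDS)
        if unknown:
            raise GroupStatsError(f"unknown analyte kind(s) {sorted(unknown)}; expected {KINDS}")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.values.to_numpy(dtype=float)) < 0:
                raise GroupStatsError("negative concentration")

    @property
    def analytes(self) -> pd.Index:
        return self.values.index

    def of_kind(self, kind: str) -> list[str]:
        return self.values.index[self.kinds == kind].tolist()

    def stage_values(self, analyte: str, design: SampleDesign) -> dict[str, np.ndarray]:
        """Non-NA replicate values per stage, in design stage order."""
        if analyte not in self.values.index:
            raise GroupStatsError(f"unknown analyte {analyte!r}")
        row = self.values.loc[analyte]
        out: dict[str, np.ndarray] = {}
        for stage in design.stages:
            vals = row[design.samples_of(stage)].to_numpy(dtype=float)
            out[stage] = vals[~np.isnan(vals)]
        return out


@dataclass
class AnovaResult:
    f: float
    p: float
    mse: float
    df_between: int
    df_error: int
    degenerate: bool = False  # all observations identical: F is 0/0


@dataclass
class DuncanResult:
    analyte: str
    means: pd.Series          # group -> mean, sorted descending
    sds: pd.Series
    letters: pd.Series        # group -> compact letter string
    critical_ranges: dict[int, float]  # span p -> R_p
    mse: float
    df_error: int
    alpha: float

    def share_letter(self, g1: str, g2: str) -> bool:
        return bool(set(self.letters[g1]) & set(self.letters[g2]))


def one_way_anova(groups: dict[str, np.ndarray] | list[np.ndarray]) -> AnovaResult:
    """Between/within decomposition for >=2 groups of >=2 replicates."""
    arrays = list(groups.values()) if isinstance(groups, dict) else [np.asarray(g) for g in groups]
    if len(arrays) < 2:
        raise GroupStatsError("ANOVA needs at least two groups")
    for i, g in enumerate(arrays):
        if len(g) < 2:
            raise GroupStatsError(f"group {i} has fewer than 2 values")
    arrays = [np.asarray(g, dtype=float) for g in arrays]
    ns = np.array([len(g) for g in arrays])
    means = np.array([g.mean() for g in arrays])
    grand = np.concatenate(arrays).mean()
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(arrays, means)))
    df_b = len(arrays) - 1
    df_e = int(ns.sum()) - len(arrays)
    mse = ss_within / df_e
    if mse == 0.0:
        if ss_between == 0.0:
            # every observation identical: F is 0/0; report the null outcome
            return AnovaResult(f=0.0, p=1.0, mse=0.0, df_between=df_b, df_error=df_e,
                               degenerate=True)
        return AnovaResult(f=np.inf, p=0.0, mse=0.0, df_between=df_b, df_error=df_e,
                           degenerate=True)
    f = (ss_between / df_b) / mse
    p = float(stats.f.sf(f, df_b, df_e))
    return AnovaResult(f=float(f), p=p, mse=mse, df_between=df_b, df_error=df_e)


@lru_cache(maxsize=4096)
def studentized_range_quantile(upper_tail: float, n_means: int, df: float) -> float:
    """q such that P(Q > q) = upper_tail for the studentized range of
    ``n_means`` means with ``df`` error degrees of freedom.

    Computed by numerical inversion of the studentized-range CDF; no lookup
    tables are shipped.
    """
    if n_means < 2:
        raise GroupStatsError("studentized range needs >= 2 means")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy integrates numerically and may warn
        return float(stats.studentized_range.ppf(1.0 - upper_tail, n_means, df))


def duncan_protection_level(alpha: float, span: int) -> float:
    """alpha_p = 1 - (1 - alpha)^(p-1) for a span of p ordered means."""
    return 1.0 - (1.0 - alpha) ** (span - 1)


def duncan_mrt(
    groups: dict[str, np.ndarray],
    alpha: float = 0.05,
    analyte: str = "",
) -> DuncanResult:
    """Duncan's multiple range test with compact letter display.

    Unbalanced replicate counts are handled with the harmonic mean of the
    group sizes (warned). Two groups share a letter iff the procedure does
    not separate them.
    """
    anova = one_way_anova(groups)
    names = list(groups)
    ns = np.array([len(groups[g]) for g in names], dtype=float)
    if len(set(ns)) > 1:
        warnings.warn("unbalanced groups: using harmonic-mean replicate count", stacklevel=2)
        r = len(ns) / (1.0 / ns).sum()
    else:
        r = float(ns[0])

    means = pd.Series({g: float(np.mean(groups[g])) for g in names})
    sds = pd.Series({g: float(np.std(groups[g], ddof=1)) for g in names})
    # sort descending; deterministic tie-break on group name
    order = sorted(names, key=lambda g: (-means[g], g))
    means = means[order]
    sds = sds[order]
    k = len(order)

    critical: dict[int, float] = {}
    for span in range(2, k + 1):
        if anova.mse == 0.0:
            critical[span] = 0.0
        else:
            q = studentized_range_quantile(duncan_protection_level(alpha, span), span,
                                           anova.df_error)
            critical[span] = q * np.sqrt(anova.mse / r)

    # Homogeneous (not-separated) intervals on the sorted order. Process
    # spans widest-first; a range inside an already-homogeneous range is
    # never tested (Duncan's protection rule).
    homogeneous: list[tuple[int, int]] = []

    def covered(i: int, j: int) -> bool:
        return any(a <= i and j <= b for a, b in homogeneous)

    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if covered(i, j):
                continue
            if means.iloc[i] - means.iloc[j] > critical[span]:
                continue  # separated
            homogeneous.append((i, j))
    # singletons are trivially homogeneous
    maximal = [(i, i) for i in range(k) if not covered(i, i)]
    maximal += homogeneous
    maximal.sort()

    alphabet = string.ascii_lowercase
    letters = {g: "" for g in order}
    for idx, (i, j) in enumerate(maximal):
        letter = alphabet[idx % len(alphabet)] * (idx // len(alphabet) + 1)
        for pos in range(i, j + 1):
            letters[order[pos]] += letter

    return DuncanResult(
        analyte=analyte,
        means=means,
        sds=sds,
        letters=pd.Series(letters)[order],
        critical_ranges=critical,
        mse=anova.mse,
        df_error=anova.df_error,
        alpha=alpha,
    )


def duncan_table(result: DuncanResult) -> pd.DataFrame:
    """Stage, mean, sd, letter — the per-analyte report table."""
    return pd.DataFrame(
        {
            "group": result.means.index,
            "mean": result.means.to_numpy(),
            "sd": result.sds.to_numpy(),
            "letter": result.letters.to_numpy(),
        }
    )


def compound_log2fc(
    compounds: CompoundTable,
    design: SampleDesign,
    contrast: Contrast,
    eps_rel: float = 0.01,
) -> pd.Series:
    """Per-analyte log2 fold change of stage-mean concentrations.

    Analyte units differ, so the pseudocount is relative: eps = eps_rel times
    the analyte's global (non-NA) mean concentration.
    """
    stage_a = design.stage_of(contrast.group_a[0])
    stage_b = design.stage_of(contrast.group_b[0])
    out = {}
    for analyte in compounds.analytes:
        row = compounds.values.loc[analyte]
        a = row[design.samples_of(stage_a)].to_numpy(dtype=float)
        b = row[design.samples_of(stage_b)].to_numpy(dtype=float)
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if a.size == 0 or b.size == 0:
            raise GroupStatsError(
                f"analyte {analyte!r}: no measurements in stage "
                f"{stage_a if a.size == 0 else stage_b}"
            )
        global_mean = float(np.nanmean(row.to_numpy(dtype=float)))
        eps = eps_rel * global_mean
        if global_mean == 0.0:
            eps = eps_rel  # all-zero analyte: any positive pseudocount gives lfc 0
        out[analyte] = float(np.log2((a.mean() + eps) / (b.mean() + eps)))
    return pd.Series(out, name=f"log2FC_{contrast.name}")


@dataclass
class CalibrationCurve:
    """Least-squares line concentration = slope * peak_area + intercept."""

    analyte: str
    slope: float
    intercept: float
    r_squared: float

    def predict(self, area: float | np.ndarray) -> float | np.ndarray:
        return self.slope * np.asarray(area, dtype=float) + self.intercept


def fit_calibration(areas, concentrations, analyte: str = "") -> CalibrationCurve:
    """Fit the standard curve of an assay from (peak area, concentration) pairs."""
    x = np.asarray(areas, dtype=float)
    y = np.asarray(concentrations, dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise GroupStatsError("calibration needs >= 2 distinct peak areas")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - float((resid**2).sum()) / ss_tot
    return CalibrationCurve(analyte=analyte, slope=float(slope), intercept=float(intercept),
                            r_squared=float(np.clip(r2, 0.0, 1.0)))
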