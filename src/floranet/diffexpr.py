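"""FPKM normalization, the 12-contrast scheme and DEG calling.

The analysis compares male and female flower buds across four differentiation
stages. Expression is fragment counts per gene; normalization is FPKM
(fragments per kilobase of transcript per million mapped fragments),

    FPKM_gi = c_gi * 1e9 / (N_i * L_g),

with ``N_i`` the library size (column total of the count matrix) and ``L_g``
the gene length in bp. Differential genes per contrast are those with
|log2FC| > 1 and p < 0.05, where the fold change is computed between group
mean FPKM with a pseudocount and significance comes from a Welch t test on
log2(FPKM + 1) (a documented, swappable surrogate for a count-model test;
all downstream logic only consumes the per-gene log2FC / p / call columns).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import SampleDesign

#: The fixed comparison scheme over the 8-stage two-sex design: four male
#: stage transitions, four female stage transitions and four stage-matched
#: cross-sex comparisons. "up" always refers to the first-named group.
CONTRAST_NAMES: tuple[str, ...] = (
    "M2vsM1", "M3vsM2", "M3vsM1", "M4vsM3",
    "F2vsF1", "F3vsF2", "F3vsF1", "F4vsF3",
    "M1vsF1", "M2vsF2", "M3vsF3", "M4vsF4",
)

CROSS_SEX_CONTRASTS: tuple[str, ...] = ("M1vsF1", "M2vsF2", "M3vsF3", "M4vsF4")


class DiffExprError(ValueError):
    pass


@dataclass
class CountMatrix:
    """Integer fragment counts (genes x samples) with gene lengths in bp."""

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        if not (self.counts.index == self.lengths.index).all():
            raise DiffExprError("gene order of counts and lengths differ")
        if (self.counts.to_numpy() < 0).any():
            raise DiffExprError("negative counts")
        if (self.lengths.to_numpy() <= 0).any():
            raise DiffExprError("non-positive gene lengths")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class FpkmMatrix:
    """Length- and depth-normalized expression (genes x samples)."""

    fpkm: pd.DataFrame
    lengths: pd.Series

    @property
    def gene_ids(self) -> pd.Index:
        return self.fpkm.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.fpkm.columns


@dataclass(frozen=True)
class Contrast:
    """A named group-A-vs-group-B comparison; up = higher in A."""

    name: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise DiffExprError(f"contrast {self.name}: empty group")
        if set(self.group_a) & set(self.group_b):
            raise DiffExprError(f"contrast {self.name}: overlapping groups")

    def reversed(self) -> "Contrast":
        a, _, b = self.name.partition("vs")
        return Contrast(f"{b}vs{a}", self.group_b, self.group_a)


@dataclass
class ContrastResult:
    """Per-gene log2FC, p and up/down/ns call for one comparison."""

    contrast: str
    table: pd.DataFrame  # columns: baseMeanA, baseMeanB, log2FC, p, call

    @property
    def up(self) -> set[str]:
        return set(self.table.index[self.table["call"] == "up"])

    @property
    def down(self) -> set[str]:
        return set(self.table.index[self.table["call"] == "down"])

    @property
    def n_up(self) -> int:
        return int((self.table["call"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["call"] == "down").sum())


def compute_fpkm(counts: CountMatrix) -> FpkmMatrix:
    """FPKM_gi = c_gi * 1e9 / (N_i * L_g).

    Doubling every count of a sample leaves its FPKM column unchanged, and
    per sample the identity sum_g FPKM_gi * L_g / 1e9 = 1 holds exactly.
    """
    n = counts.library_sizes.to_numpy(dtype=float)
    if (n == 0).any():
        zero = counts.sample_ids[n == 0].tolist()
        raise DiffExprError(f"zero library size for sample(s) {zero}")
    c = counts.counts.to_numpy(dtype=float)
    l = counts.lengths.to_numpy(dtype=float)
    fpkm = c * 1e9 / (n[None, :] * l[:, None])
    return FpkmMatrix(
        fpkm=pd.DataFrame(fpkm, index=counts.gene_ids, columns=counts.sample_ids),
        lengths=counts.lengths,
    )


def build_contrast_scheme(design: SampleDesign) -> list[Contrast]:
    """The fixed 12-comparison scheme over stages M1..M4 and F1..F4.

    Fails fast, listing every absent stage, rather than emitting a partial
    scheme.
    """
    present = set(design.stages)
    needed = {s for name in CONTRAST_NAMES for s in name.split("vs")}
    absent = sorted(needed - present)
    if absent:
        raise DiffExprError(f"design is missing stage(s) {absent}; no contrasts built")
    scheme = []
    for name in CONTRAST_NAMES:
        a, _, b = name.partition("vs")
        scheme.append(Contrast(name, tuple(design.samples_of(a)), tuple(design.samples_of(b))))
    return scheme


def log2_fold_change(fpkm: FpkmMatrix, contrast: Contrast, epsilon: float = 1.0) -> pd.Series:
    """log2((mean_A FPKM + eps) / (mean_B FPKM + eps)) per gene."""
    if epsilon <= 0:
        raise DiffExprError("epsilon must be positive")
    mean_a = fpkm.fpkm[list(contrast.group_a)].mean(axis=1)
    mean_b = fpkm.fpkm[list(contrast.group_b)].mean(axis=1)
    return pd.Series(
        np.log2((mean_a + epsilon) / (mean_b + epsilon)),
        index=fpkm.gene_ids,
        name=f"log2FC_{contrast.name}",
    )


# Floor on per-group variance; makes identical groups yield t=0, p=1 instead
# of 0/0, without affecting any group with real replicate scatter.
VARIANCE_FLOOR = 1e-8


def welch_test(log_values: pd.DataFrame, contrast: Contrast) -> pd.Series:
    """Vectorized Welch t test (Satterthwaite df) per gene, two-sided p.

    ``log_values`` is expected on the log2(FPKM + 1) scale. Symmetric in the
    two groups; requires >= 2 replicates in each.
    """
    a = log_values[list(contrast.group_a)].to_numpy(dtype=float)
    b = log_values[list(contrast.group_b)].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise DiffExprError(
            f"contrast {contrast.name}: Welch test needs >=2 replicates per group "
            f"(got {na} and {nb})"
        )
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = np.maximum(a.var(axis=1, ddof=1), VARIANCE_FLOOR)
    vb = np.maximum(b.var(axis=1, ddof=1), VARIANCE_FLOOR)
    sa, sb = va / na, vb / nb
    t = (ma - mb) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return pd.Series(np.clip(p, 0.0, 1.0), index=log_values.index, name=f"p_{contrast.name}")


def call_degs(
    lfc: pd.Series,
    p: pd.Series,
    base_mean_a: pd.Series,
    base_mean_b: pd.Series,
    contrast_name: str,
    lfc_min: float = 1.0,
    alpha: float = 0.05,
) -> ContrastResult:
    """Apply the strict |log2FC| > lfc_min and p < alpha thresholds.

    Ties at either threshold are called ``ns``.
    """
    if not lfc.index.equals(p.index):
        raise DiffExprError("log2FC and p vectors are not gene-aligned")
    call = np.where(
        (lfc.to_numpy() > lfc_min) & (p.to_numpy() < alpha),
        "up",
        np.where((lfc.to_numpy() < -lfc_min) & (p.to_numpy() < alpha), "down", "ns"),
    )
    table = pd.DataFrame(
        {
            "baseMeanA": base_mean_a,
            "baseMeanB": base_mean_b,
            "log2FC": lfc,
            "p": p,
            "call": call,
        },
        index=lfc.index,
    )
    return ContrastResult(contrast=contrast_name, table=table)


def run_contrast(
    fpkm: FpkmMatrix,
    contrast: Contrast,
    epsilon: float = 1.0,
    lfc_min: float = 1.0,
    alpha: float = 0.05,
) -> ContrastResult:
    """Fold change + Welch p + calls for one contrast."""
    log_values = np.log2(fpkm.fpkm + 1.0)
    lfc = log2_fold_change(fpkm, contrast, epsilon=epsilon)
    p = welch_test(log_values, contrast)
    mean_a = fpkm.fpkm[list(contrast.group_a)].mean(axis=1)
    mean_b = fpkm.fpkm[list(contrast.group_b)].mean(axis=1)
    return call_degs(lfc, p, mean_a, mean_b, contrast.name, lfc_min=lfc_min, alpha=alpha)


def run_all_contrasts(
    fpkm: FpkmMatrix,
    scheme: list[Contrast],
    epsilon: float = 1.0,
    lfc_min: float = 1.0,
    alpha: float = 0.05,
) -> dict[str, ContrastResult]:
    return {
        c.name: run_contrast(fpkm, c, epsilon=epsilon, lfc_min=lfc_min, alpha=alpha)
        for c in scheme
    }


def exclusive_upregulated(family: dict[str, set[str]], target: str) -> set[str]:
    """Genes in the target set and in no other set of the family.

    This is the UpSet-style "exclusively identified" statistic: e.g. the
    up-regulated genes unique to one stage transition among the four male
    comparisons.
    """
    if not family:
        raise DiffExprError("empty DEG-set family")
    if target not in family:
        raise DiffExprError(f"target {target!r} not among {sorted(family)}")
    others: set[str] = set()
    for name, genes in family.items():
        if name != target:
            others |= genes
    return set(family[target]) - others
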