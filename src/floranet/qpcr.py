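"""2^-ddCt relative quantification and RNA-seq/qPCR concordance.

Target gene Ct values are normalized to a reference gene per sample
(dCt = Ct_target - Ct_reference), then to a calibrator sample
(ddCt = dCt - dCt_calibrator), and exponentiated:

    RQ = 2 ** (-ddCt).

Technical replicates are averaged (arithmetic mean of Ct) before dCt.
Amplification efficiency is fixed at 2, which is what the method's name
assumes; efficiency correction from dilution series is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import SampleDesign
from .diffexpr import Contrast


class QpcrError(ValueError):
    pass


@dataclass
class CtTable:
    """Ct values per (sample, gene, technical replicate), long format.

    ``table`` columns: sample, gene, ct. The reference gene must be measured
    in every sample; the calibrator sample anchors RQ = 1.
    """

    table: pd.DataFrame
    reference_gene: str
    calibrator_sample: str

    def __post_init__(self) -> None:
        required = {"sample", "gene", "ct"}
        missing = required - set(self.table.columns)
        if missing:
            raise QpcrError(f"Ct table missing columns {sorted(missing)}")
        if (self.table["ct"].to_numpy(dtype=float) <= 0).any():
            raise QpcrError("non-positive Ct value")
        samples = set(self.table["sample"])
        if self.calibrator_sample not in samples:
            raise QpcrError(f"calibrator sample {self.calibrator_sample!r} has no Ct rows")
        ref_samples = set(self.table.loc[self.table["gene"] == self.reference_gene, "sample"])
        lacking = samples - ref_samples
        if lacking:
            raise QpcrError(
                f"reference gene {self.reference_gene!r} missing in sample(s) {sorted(lacking)}"
            )

    @property
    def genes(self) -> list[str]:
        return [g for g in dict.fromkeys(self.table["gene"]) if g != self.reference_gene]

    def mean_ct(self) -> pd.DataFrame:
        """Technical replicates averaged: samples x genes matrix of Ct."""
        return self.table.pivot_table(index="sample", columns="gene", values="ct",
                                      aggfunc="mean")


@dataclass
class RelativeExpression:
    """RQ = 2^-ddCt per (sample, gene); RQ == 1 at the calibrator."""

    rq: pd.DataFrame  # samples x genes
    calibrator_sample: str

    def log2(self) -> pd.DataFrame:
        return np.log2(self.rq)


def delta_delta_ct(ct: CtTable) -> RelativeExpression:
    """Relative expression by the 2^-ddCt method."""
    mean_ct = ct.mean_ct()
    ref = mean_ct[ct.reference_gene]
    if ref.isna().any():
        bad = ref.index[ref.isna()].tolist()
        raise QpcrError(f"reference Ct missing for sample(s) {bad}")
    targets = [g for g in mean_ct.columns if g != ct.reference_gene]
    dct = mean_ct[targets].sub(ref, axis=0)
    if ct.calibrator_sample not in dct.index:
        raise QpcrError(f"calibrator {ct.calibrator_sample!r} absent after aggregation")
    ddct = dct.sub(dct.loc[ct.calibrator_sample], axis=1)
    if ddct.isna().any().any():
        missing = [
            (s, g) for s in ddct.index for g in ddct.columns if pd.isna(ddct.loc[s, g])
        ]
        raise QpcrError(f"missing target Ct for {missing[:5]}{'...' if len(missing) > 5 else ''}")
    return RelativeExpression(rq=2.0 ** (-ddct), calibrator_sample=ct.calibrator_sample)


def stage_log2fc(
    rel: RelativeExpression, design: SampleDesign, contrast: Contrast
) -> pd.Series:
    """qPCR log2 fold change per gene: mean log2 RQ in group A minus group B."""
    log_rq = rel.log2()
    a = [s for s in contrast.group_a if s in log_rq.index]
    b = [s for s in contrast.group_b if s in log_rq.index]
    if not a or not b:
        raise QpcrError(f"contrast {contrast.name}: no qPCR samples in one of the groups")
    return log_rq.loc[a].mean(axis=0) - log_rq.loc[b].mean(axis=0)


def platform_concordance(qpcr_lfc, rnaseq_lfc) -> tuple[float, float]:
    """Pearson r and R^2 between log2 fold changes of the two platforms.

    Inputs must be aligned (gene, contrast) vectors of equal length >= 3.
    """
    x = np.asarray(qpcr_lfc, dtype=float)
    y = np.asarray(rnaseq_lfc, dtype=float)
    if x.shape != y.shape:
        raise QpcrError("fold-change vectors are not aligned")
    if x.size < 3:
        raise QpcrError("concordance needs >= 3 (gene, contrast) pairs")
    r = float(stats.pearsonr(x, y).statistic)
    return r, r * r
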