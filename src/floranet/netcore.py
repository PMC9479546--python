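"""Mixed transcript/hormone/sugar Pearson co-expression network and hub
selection.

Candidate features (curated genes plus measured phytohormones and sugars)
are profiled over the shared 24-sample layout. Every unordered feature pair
is scored with the Pearson coefficient r; significance uses the exact null
distribution via t = r * sqrt((n-2) / (1-r^2)) with n-2 degrees of freedom.
An edge is kept iff |r| >= r_min and p < alpha_edge.

Hubs ("crucial factors") are selected with a composite rule: a node must sit
in the top 40% of network degrees AND in the top 40% of the RMS log2 fold
change s_v = sqrt((lfc_M3vsF3^2 + lfc_M4vsF4^2)/2) over the two late
cross-sex comparisons. Both cutoffs are top-k order statistics
(k = ceil(0.4 * m)) with ties at the cutoff included, so the result is
deterministic and independent of feature input order. The degree cutoff is
taken over nodes actually present in the network (degree >= 1) — degree is a
property of the drawn network and an isolated candidate cannot be a hub —
while the RMS cutoff ranks all scored candidates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import FpkmMatrix
from .groupstats import CompoundTable

FEATURE_KINDS = ("gene", "hormone", "sugar")


class NetworkError(ValueError):
    pass


@dataclass
class NetParams:
    """Edge and hub thresholds.

    r_min:            minimum |Pearson r| for an edge (default 0.8).
    alpha_edge:       edge p-value threshold (default 0.05).
    degree_quantile:  degree rank cutoff; 0.60 keeps the top 40% of degrees.
    score_quantile:   RMS-lfc rank cutoff; 0.60 keeps the top 40% of scores.
    """

    r_min: float = 0.8
    alpha_edge: float = 0.05
    degree_quantile: float = 0.60
    score_quantile: float = 0.60

    def __post_init__(self) -> None:
        if not 0 < self.r_min < 1:
            raise NetworkError("r_min must be in (0, 1)")
        for q in (self.degree_quantile, self.score_quantile):
            if not 0 < q < 1:
                raise NetworkError("quantiles must be in (0, 1)")


@dataclass
class FeatureMatrix:
    """Z-standardized feature profiles over the common sample layout."""

    profiles: pd.DataFrame  # features x samples, mean 0 / sd 1 per row
    kinds: pd.Series        # feature -> gene | hormone | sugar
    excluded_constant: list[str] = field(default_factory=list)

    @property
    def feature_ids(self) -> pd.Index:
        return self.profiles.index

    @property
    def n_samples(self) -> int:
        return self.profiles.shape[1]


@dataclass(frozen=True)
class Edge:
    """Undirected co-expression edge, stored once in canonical id order."""

    u: str
    v: str
    r: float
    p: float

    def __post_init__(self) -> None:
        if self.u == self.v:
            raise NetworkError("self edge")
        if self.u > self.v:
            u, v = self.v, self.u
            object.__setattr__(self, "u", u)
            object.__setattr__(self, "v", v)


def assemble_candidates(
    fpkm: FpkmMatrix,
    compounds: CompoundTable | None,
    candidate_ids,
    log_scale: bool = True,
) -> FeatureMatrix:
    """Resolve candidate ids against expression and compound sources.

    Every id must resolve in exactly one source (a gene id in the FPKM
    matrix, or an analyte id in the compound table). Profiles are aligned to
    the FPKM sample order and z-standardized; constant profiles are excluded
    with a warning since Pearson correlation is undefined for them.

    With ``log_scale`` (the default) profiles enter as log2(value + 1), the
    usual scale for expression co-analysis; pass ``False`` to correlate the
    raw values, in which case the whole downstream hub call is exactly
    invariant to per-feature affine rescaling.
    """
    samples = list(fpkm.sample_ids)
    if compounds is not None:
        missing = [s for s in samples if s not in compounds.values.columns]
        if missing:
            raise NetworkError(f"compound table lacks sample(s) {missing}")
    rows, kinds = {}, {}
    for cid in candidate_ids:
        in_genes = cid in fpkm.gene_ids
        in_compounds = compounds is not None and cid in compounds.analytes
        if in_genes and in_compounds:
            raise NetworkError(f"candidate {cid!r} is ambiguous (gene and analyte)")
        if in_genes:
            rows[cid] = fpkm.fpkm.loc[cid, samples].to_numpy(dtype=float)
            kinds[cid] = "gene"
        elif in_compounds:
            vals = compounds.values.loc[cid, samples].to_numpy(dtype=float)
            if np.isnan(vals).any():
                raise NetworkError(f"candidate analyte {cid!r} has missing measurements")
            rows[cid] = vals
            kinds[cid] = compounds.kinds[cid]
        else:
            raise NetworkError(f"candidate {cid!r} not found in expression or compound data")
    excluded = []
    profiles = {}
    for cid, vals in rows.items():
        if log_scale:
            vals = np.log2(vals + 1.0)
        sd = vals.std(ddof=0)
        if sd == 0.0:
            excluded.append(cid)
            continue
        profiles[cid] = (vals - vals.mean()) / sd
    if excluded:
        warnings.warn(f"excluded constant profile(s): {excluded}", stacklevel=2)
        for cid in excluded:
            kinds.pop(cid)
    frame = pd.DataFrame(profiles, index=samples).T
    frame.index.name = "feature"
    return FeatureMatrix(profiles=frame, kinds=pd.Series(kinds), excluded_constant=excluded)


def pearson_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r via the exact t transform, df = n - 2.

    |r| = 1 maps to p = 0 (reported as such; no division blow-up).
    """
    r = np.asarray(r, dtype=float)
    denom = 1.0 - r * r
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(r) * np.sqrt((n - 2) / np.where(denom <= 0, np.nan, denom))
    p = 2.0 * stats.t.sf(t, n - 2)
    return np.where(denom <= 0, 0.0, np.clip(p, 0.0, 1.0))


def pearson_edges(features: FeatureMatrix, params: NetParams) -> list[Edge]:
    """Score all unordered pairs; keep |r| >= r_min and p < alpha_edge."""
    n = features.n_samples
    if n < 3:
        raise NetworkError("Pearson network needs >= 3 samples")
    ids = list(features.feature_ids)
    if len(ids) < 2:
        return []
    mat = np.corrcoef(features.profiles.to_numpy(dtype=float))
    mat = np.clip(mat, -1.0, 1.0)
    edges: list[Edge] = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            r = float(mat[i, j])
            if abs(r) < params.r_min:
                continue
            p = float(pearson_pvalue(np.array([r]), n)[0])
            if p < params.alpha_edge:
                edges.append(Edge(ids[i], ids[j], r, p))
    return edges


def node_degree(edges: list[Edge], feature_ids) -> pd.Series:
    """Incident-edge counts; isolated candidates get degree 0."""
    deg = {fid: 0 for fid in feature_ids}
    for e in edges:
        for node in (e.u, e.v):
            if node not in deg:
                raise NetworkError(f"edge endpoint {node!r} not among features")
        deg[e.u] += 1
        deg[e.v] += 1
    return pd.Series(deg, dtype=int)


def rms_lfc(lfc_m3f3: float, lfc_m4f4: float) -> float:
    """Root mean square of the two late cross-sex log2 fold changes."""
    return math.sqrt((lfc_m3f3**2 + lfc_m4f4**2) / 2.0)


def _top_k_cutoff(values: np.ndarray, keep_fraction: float) -> float:
    """Smallest value still inside the top ``keep_fraction`` of ``values``.

    k = ceil(keep_fraction * len); ties at the cutoff pass the >= test.
    """
    k = max(1, math.ceil(keep_fraction * values.size))
    return float(np.sort(values)[::-1][k - 1])


def select_hubs(
    features: FeatureMatrix,
    edges: list[Edge],
    scores: pd.Series,
    params: NetParams = None,
) -> pd.DataFrame:
    """Composite hub call: top-degree AND top-RMS-lfc, ties included.

    ``scores`` maps every feature id to its RMS log2FC s_v. Returns the full
    table (feature, kind, degree, rms_lfc, is_hub) in feature order. Raising
    either quantile can only shrink the hub set.
    """
    if params is None:
        params = NetParams()
    ids = list(features.feature_ids)
    missing = [fid for fid in ids if fid not in scores.index]
    if missing:
        raise NetworkError(f"no RMS score for feature(s) {missing[:5]}")
    degrees = node_degree(edges, ids)
    s = scores.loc[ids].astype(float)
    if (s < 0).any():
        raise NetworkError("RMS scores must be non-negative")

    in_network = degrees[degrees > 0]
    if in_network.empty:
        warnings.warn("network has no edges: empty hub set", stacklevel=2)
        is_hub = pd.Series(False, index=ids)
    else:
        deg_cut = _top_k_cutoff(in_network.to_numpy(dtype=float),
                                1.0 - params.degree_quantile)
        score_cut = _top_k_cutoff(s.to_numpy(), 1.0 - params.score_quantile)
        is_hub = (degrees >= max(deg_cut, 1)) & (s >= score_cut)
    return pd.DataFrame(
        {
            "feature": ids,
            "kind": features.kinds.loc[ids].to_numpy(),
            "degree": degrees.loc[ids].to_numpy(),
            "rms_lfc": s.to_numpy(),
            "is_hub": is_hub.loc[ids].to_numpy(),
        }
    )


def build_graph(features: FeatureMatrix, edges: list[Edge], hub_table: pd.DataFrame) -> nx.Graph:
    """networkx graph carrying node kind/degree/RMS/hub and edge r/p."""
    g = nx.Graph()
    indexed = hub_table.set_index("feature")
    for fid in features.feature_ids:
        row = indexed.loc[fid]
        g.add_node(
            fid,
            kind=str(row["kind"]),
            degree=int(row["degree"]),
            rms_lfc=float(row["rms_lfc"]),
            is_hub=bool(row["is_hub"]),
        )
    for e in edges:
        g.add_edge(e.u, e.v, r=float(e.r), p=float(e.p))
    return g
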