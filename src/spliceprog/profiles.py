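"""Tissue and cell-type inclusion profiles.

Tissue-enrichment/depletion calling across tissue groups, grouping of
regulated exons by tissue (shared / eye / neural) and by neural cell
type (glia-shared / PR-up / KC-down / PR-down / pan-neuronal), last-exon
usage from junction reads, correlation-based sample distances, sample
merging and variable-exon selection.

Per-tissue PSI is the mean over that tissue's samples after quality
masking.  Missing values are handled pairwise-complete in correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import JunctionCountTable, PsiMatrix

__all__ = [
    "call_tissue_profile",
    "group_emic_by_tissue",
    "group_emic_by_celltype",
    "LastExonUsage",
    "last_exon_usage",
    "sample_distance_matrix",
    "merge_samples",
    "variable_exon_set",
]


def _per_tissue_mean(matrix: PsiMatrix, tissue_col: str) -> pd.DataFrame:
    meta = matrix.metadata
    tissues = sorted(meta[tissue_col].dropna().unique())
    cols = {}
    for t in tissues:
        samp = matrix.samples_where(**{tissue_col: t})
        cols[t] = matrix.psi[samp].mean(axis=1)
    return pd.DataFrame(cols)


def call_tissue_profile(
    matrix: PsiMatrix,
    tissue_col: str = "tissue_group",
    enrich: tuple[float, float] = (25.0, 15.0),
    mutual_exclusions: Sequence[tuple[str, str]] = (("neural", "sensory"),),
) -> pd.DataFrame:
    """Per-event tissue-enrichment and -depletion calls.

    A tissue is enriched for an event iff PSI_t − mean(others) ≥ 25 and
    PSI_t − max(others) ≥ 15 (depleted with mirrored signs against
    min(others)).  Tissues listed in ``mutual_exclusions`` are removed
    from each other's "others" (neural and sensory share cell types).
    Events covered in fewer than two tissue groups are skipped.
    """
    d_mean, d_ext = enrich
    pt = _per_tissue_mean(matrix, tissue_col)
    tissues = list(pt.columns)
    excl = {t: set() for t in tissues}
    for a, b in mutual_exclusions:
        if a in excl and b in excl:
            excl[a].add(b)
            excl[b].add(a)
    n_cov = pt.notna().sum(axis=1)
    rows: dict[str, pd.Series] = {}
    enriched = {t: pd.Series(False, index=pt.index) for t in tissues}
    depleted = {t: pd.Series(False, index=pt.index) for t in tissues}
    for t in tissues:
        others = [o for o in tissues if o != t and o not in excl[t]]
        om = pt[others]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            omean, omax, omin = om.mean(axis=1), om.max(axis=1), om.min(axis=1)
        ok = pt[t].notna() & om.notna().any(axis=1)
        enriched[t] = (ok & (pt[t] - omean >= d_mean) & (pt[t] - omax >= d_ext)).fillna(False)
        depleted[t] = (ok & (omean - pt[t] >= d_mean) & (omin - pt[t] >= d_ext)).fillna(False)
    res = pt.copy()
    res.columns = [f"psi_{t}" for t in tissues]
    res["n_covered_tissues"] = n_cov
    res["enriched_in"] = [
        ",".join(t for t in tissues if enriched[t][e]) for e in pt.index
    ]
    res["depleted_in"] = [
        ",".join(t for t in tissues if depleted[t][e]) for e in pt.index
    ]
    res.loc[n_cov < 2, ["enriched_in", "depleted_in"]] = np.nan
    return res


def group_emic_by_tissue(
    emic_events: Sequence[str],
    matrix: PsiMatrix,
    tissue_col: str = "tissue",
    neural_tissues: Sequence[str] = ("brain", "eye", "ganglion"),
    eye: str = "eye",
    brain_like: Sequence[str] = ("brain", "ganglion"),
    shared_psi: float = 40.0,
    shared_dpsi: float = 15.0,
    eye_dpsi: float = 20.0,
) -> pd.Series:
    """Assign regulated exons to shared / eye / neural tissue groups.

    Sequential, exclusive: *shared* when any non-neural tissue reaches
    PSI ≥ 40 or the neural-vs-non-neural ΔPSI ≤ 15; *eye* when the
    eye-vs-(brain, ganglion mean) ΔPSI ≥ 20; else *neural*.
    """
    pt = _per_tissue_mean(matrix, tissue_col)
    missing = [t for t in (eye, *brain_like) if t not in pt.columns]
    if missing:
        warnings.warn(f"tissues absent from matrix: {missing}; eye group undefined")
    non_neural = [t for t in pt.columns if t not in set(neural_tissues)]
    out = {}
    for ev in emic_events:
        if ev not in pt.index:
            out[ev] = "neural"
            continue
        row = pt.loc[ev]
        nn = row[non_neural].dropna()
        neural_mean = row[[t for t in neural_tissues if t in pt.columns]].mean()
        if (len(nn) and nn.max() >= shared_psi) or (
            len(nn) and np.isfinite(neural_mean) and neural_mean - nn.mean() <= shared_dpsi
        ):
            out[ev] = "shared"
            continue
        if eye in pt.columns and not missing:
            ref = row[[t for t in brain_like]].mean()
            if np.isfinite(row[eye]) and np.isfinite(ref) and row[eye] - ref >= eye_dpsi:
                out[ev] = "eye"
                continue
        out[ev] = "neural"
    return pd.Series(out, name="tissue_group")


def group_emic_by_celltype(
    emic_events: Sequence[str],
    matrix: PsiMatrix,
    class_col: str = "cell_class",
    glia: str = "glia",
    photoreceptor: str = "photoreceptor",
    kenyon: str = "kenyon",
    glia_psi: float = 50.0,
    dpsi: float = 25.0,
) -> pd.Series:
    """Assign regulated exons to the five neural cell-type groups.

    Applied sequentially and exclusively: (i) glia-shared: PSI ≥ 50 in any
    glial sample; (ii) PR-up: ΔPSI ≥ 25 between photoreceptors and the
    mean of other neuronal types; (iii) KC-down: ΔPSI ≤ −25 for Kenyon
    cells; (iv) PR-down: ΔPSI ≤ −25 for photoreceptors; (v) pan-neuronal.
    "Other neuronal types" excludes glia and the focal type.
    """
    meta = matrix.metadata
    glial = matrix.samples_where(**{class_col: glia})
    if not glial:
        warnings.warn("no glial samples; glia-shared group skipped")
    neuronal = [s for s in matrix.samples if meta.at[s, class_col] != glia]
    types = sorted({meta.at[s, class_col] for s in neuronal})
    type_mean = {
        t: matrix.psi[[s for s in neuronal if meta.at[s, class_col] == t]].mean(axis=1)
        for t in types
    }
    out = {}
    for ev in emic_events:
        if glial and matrix.psi.loc[ev, glial].max() >= glia_psi:
            out[ev] = "glia-shared"
            continue
        def focal_delta(focal: str) -> float:
            if focal not in type_mean:
                return np.nan
            others = [type_mean[t][ev] for t in types if t != focal]
            others = [v for v in others if np.isfinite(v)]
            if not others or not np.isfinite(type_mean[focal][ev]):
                return np.nan
            return type_mean[focal][ev] - float(np.mean(others))

        d_pr = focal_delta(photoreceptor)
        d_kc = focal_delta(kenyon)
        if np.isfinite(d_pr) and d_pr >= dpsi:
            out[ev] = "PR-up"
        elif np.isfinite(d_kc) and d_kc <= -dpsi:
            out[ev] = "KC-down"
        elif np.isfinite(d_pr) and d_pr <= -dpsi:
            out[ev] = "PR-down"
        else:
            out[ev] = "pan-neuronal"
    return pd.Series(out, name="celltype_group")


@dataclass
class LastExonUsage:
    """Junction-read proportions from one shared donor to competing acceptors."""

    gene_id: str
    donor: int
    acceptors: tuple[int, ...]
    counts: dict[int, int] = field(default_factory=dict)
    proportions: dict[int, float] | None = None
    labels: dict[int, str] | None = None

    @property
    def defined(self) -> bool:
        return self.proportions is not None


def last_exon_usage(
    junctions: JunctionCountTable,
    gene: str,
    donor: int,
    acceptors: Sequence[int],
    labels: Mapping[int, str] | None = None,
) -> LastExonUsage:
    """Proportion of junction reads from ``donor`` to each acceptor.

    Absent (gene, donor, acceptor) rows count as zero.  When the total is
    zero the proportions are flagged undefined rather than NaN-propagated.
    """
    counts = {a: junctions.get(gene, donor, a) for a in acceptors}
    total = sum(counts.values())
    props = {a: c / total for a, c in counts.items()} if total > 0 else None
    return LastExonUsage(gene, donor, tuple(acceptors), counts, props,
                         dict(labels) if labels else None)


def sample_distance_matrix(
    matrix: PsiMatrix,
    events: Sequence[str] | None = None,
    min_shared: int = 3,
) -> pd.DataFrame:
    """(1 − Pearson correlation) distances between samples.

    Correlations are pairwise-complete over the selected events; pairs
    sharing fewer than ``min_shared`` informative events get NaN.
    """
    psi = matrix.psi if events is None else matrix.psi.loc[list(events)]
    samples = list(psi.columns)
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    X = psi.to_numpy(dtype=float)
    n = len(samples)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = np.isfinite(X[:, i]) & np.isfinite(X[:, j])
            if ok.sum() < min_shared:
                D[i, j] = D[j, i] = np.nan
                continue
            a, b = X[ok, i], X[ok, j]
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                D[i, j] = D[j, i] = np.nan
                continue
            r = float(np.corrcoef(a, b)[0, 1])
            D[i, j] = D[j, i] = 1.0 - r
    return pd.DataFrame(D, index=samples, columns=samples)


def merge_samples(
    matrix: PsiMatrix,
    grouping: Mapping[str, str],
    weights: Mapping[str, float] | None = None,
) -> PsiMatrix:
    """Merge related samples into group-level pseudo-samples.

    Merged PSI is the (coverage-)weighted mean of informative member
    cells; merged quality is the best member quality.  Metadata keeps the
    columns that are constant within each group.
    """
    from .io_core import QUALITY_ORDER, _QRANK

    groups: dict[str, list[str]] = {}
    for s, g in grouping.items():
        groups.setdefault(g, []).append(s)
    for g, members in groups.items():
        if not members:
            raise ValueError(f"empty group {g!r}")
    new_psi, new_q, meta_rows = {}, {}, {}
    for g, members in groups.items():
        sub = matrix.psi[members]
        w = np.array([1.0 if weights is None else float(weights[m]) for m in members])
        vals = sub.to_numpy(dtype=float)
        wm = np.where(np.isfinite(vals), w[None, :], 0.0)
        tot = wm.sum(axis=1)
        with np.errstate(invalid="ignore"):
            merged = np.where(tot > 0, np.nansum(vals * wm, axis=1) / np.where(tot > 0, tot, 1), np.nan)
        new_psi[g] = pd.Series(merged, index=sub.index)
        qsub = matrix.quality[members]
        new_q[g] = qsub.apply(lambda row: QUALITY_ORDER[max(_QRANK[q] for q in row)], axis=1)
        mm = matrix.metadata.loc[members]
        meta_rows[g] = {
            c: (mm[c].iloc[0] if mm[c].nunique(dropna=False) == 1 else None)
            for c in mm.columns
        }
    psi = pd.DataFrame(new_psi)
    qual = pd.DataFrame(new_q)
    meta = pd.DataFrame(meta_rows).T
    meta.index.name = matrix.metadata.index.name
    return PsiMatrix(psi, qual, meta,
                     None if matrix.event_info is None else matrix.event_info.copy())


def variable_exon_set(
    matrix: PsiMatrix,
    samples: Sequence[str] | None = None,
    range_thresh: float = 20.0,
) -> list[str]:
    """Events whose PSI range (max − min) across the samples is ≥ threshold.

    Events with fewer than two informative samples are excluded.
    """
    psi = matrix.psi if samples is None else matrix.psi[list(samples)]
    n = psi.notna().sum(axis=1)
    rng = psi.max(axis=1) - psi.min(axis=1)
    keep = (n >= 2) & (rng >= range_thresh)
    return [e for e in psi.index if keep[e]]
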