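"""ΔPSI-based event classification.

Implements the regulated-event calling used throughout the package:
knockout-vs-control ΔPSI with per-stratum (per-sex) confirmation, the
three-way eMIC-dependent / eMIC-sensitive / eMIC-independent labels for
the fly, mouse and human-overexpression study designs, sex-differential
calls, the four control exon sets used as comparison groups for the
cis-regulatory analyses, protein-impact prediction and RBP-perturbation
group-shift tests.

Sign convention: ΔPSI = mean(test) − mean(reference), i.e. mutant −
control, so exons skipped upon loss of the regulator have negative ΔPSI.
The "PSI range" requirement is interpreted as a range gap,
min(reference PSIs) − max(test PSIs) ≥ gap for down-regulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import PsiMatrix, ExonEvent, GeneAnnotation, SequenceStore, Transcript
from .stats import bh_fdr, mann_whitney_u

__all__ = [
    "LABEL_DEPENDENT",
    "LABEL_SENSITIVE",
    "LABEL_INDEPENDENT",
    "LABEL_NO_COVERAGE",
    "delta_psi",
    "call_regulated_events",
    "classify_emic",
    "call_sex_differential",
    "ControlSets",
    "define_control_sets",
    "ProteinImpact",
    "classify_protein_impact",
    "group_shift_test",
]

LABEL_DEPENDENT = "eMIC-dependent"
LABEL_SENSITIVE = "eMIC-sensitive"
LABEL_INDEPENDENT = "eMIC-independent"
LABEL_NO_COVERAGE = "no-coverage"


# ---------------------------------------------------------------------------
# ΔPSI
# ---------------------------------------------------------------------------

def delta_psi(
    matrix: PsiMatrix,
    test_group: Sequence[str],
    reference_group: Sequence[str],
    strata: Mapping[str, tuple[Sequence[str], Sequence[str]]] | None = None,
) -> pd.DataFrame:
    """Per-event ΔPSI = mean(test) − mean(reference) over informative cells.

    ``strata`` maps a stratum name (e.g. a sex) to its (test, reference)
    sample subsets; a per-stratum ΔPSI is reported only when both subsets
    have at least one informative sample for the event.  Events without
    any informative sample in either group get ``dpsi`` NaN (no-coverage),
    never an exception.

    Also reports the range gap: ``range_gap_down`` = min(reference) −
    max(test) (positive when every reference sample exceeds every test
    sample), and its mirror ``range_gap_up`` = min(test) − max(reference).
    """
    test_group, reference_group = list(test_group), list(reference_group)
    if not test_group or not reference_group:
        raise ValueError("test and reference groups must be non-empty")
    tpsi = matrix.psi[test_group]
    rpsi = matrix.psi[reference_group]
    out = pd.DataFrame(index=matrix.psi.index)
    out["mean_test"] = tpsi.mean(axis=1)
    out["mean_ref"] = rpsi.mean(axis=1)
    out["n_test"] = tpsi.notna().sum(axis=1)
    out["n_ref"] = rpsi.notna().sum(axis=1)
    out["dpsi"] = out["mean_test"] - out["mean_ref"]
    out["max_test"] = tpsi.max(axis=1)
    out["min_test"] = tpsi.min(axis=1)
    out["range_gap_down"] = rpsi.min(axis=1) - tpsi.max(axis=1)
    out["range_gap_up"] = tpsi.min(axis=1) - rpsi.max(axis=1)
    if strata:
        for name, (tsub, rsub) in strata.items():
            ts, rs = matrix.psi[list(tsub)], matrix.psi[list(rsub)]
            ok = (ts.notna().sum(axis=1) >= 1) & (rs.notna().sum(axis=1) >= 1)
            d = ts.mean(axis=1) - rs.mean(axis=1)
            out[f"dpsi_{name}"] = d.where(ok)
    return out


def call_regulated_events(
    dp: pd.DataFrame,
    dpsi_thresh: float = 20.0,
    stratum_thresh: float = 15.0,
) -> pd.DataFrame:
    """Call regulated events from a :func:`delta_psi` table.

    Down-regulated iff ΔPSI ≤ −dpsi_thresh and every per-stratum ΔPSI
    ≤ −stratum_thresh (mirrored for up).  Events with a missing stratum
    ΔPSI are not callable in either direction.
    """
    strat_cols = [c for c in dp.columns if c.startswith("dpsi_")]
    d = dp["dpsi"]
    strata_ok = dp[strat_cols].notna().all(axis=1) if strat_cols else pd.Series(True, index=dp.index)
    down = (d <= -dpsi_thresh) & strata_ok
    up = (d >= dpsi_thresh) & strata_ok
    for c in strat_cols:
        down &= dp[c] <= -stratum_thresh
        up &= dp[c] >= stratum_thresh
    direction = pd.Series("none", index=dp.index, dtype=object)
    direction[down.fillna(False)] = "down"
    direction[up.fillna(False)] = "up"
    res = pd.DataFrame({"direction": direction, "dpsi": d})
    res["regulated"] = direction != "none"
    return res


# ---------------------------------------------------------------------------
# eMIC presets
# ---------------------------------------------------------------------------

def _group_cols(matrix: PsiMatrix, **criteria) -> list[str]:
    return matrix.samples_where(**criteria)


def _comparison(matrix, test_cols, ref_cols, sexes, sex_col, meta):
    """ΔPSI stats for one mutant-vs-control comparison, with per-sex strata."""
    strata = {}
    for sex in sexes:
        t = [c for c in test_cols if meta.at[c, sex_col] == sex]
        r = [c for c in ref_cols if meta.at[c, sex_col] == sex]
        if t and r:
            strata[sex] = (t, r)
    return delta_psi(matrix, test_cols, ref_cols, strata=strata)


def classify_emic(
    matrix: PsiMatrix,
    preset: str,
    mutant: str = "mutant",
    control: str = "control",
    oe_dpsi: pd.Series | None = None,
    dpsi_thresh: float = 20.0,
    sex_thresh: float = 15.0,
    sensitive_thresh: float = 10.0,
    low_psi: float = 1.0,
    oe_thresh: float = 15.0,
) -> pd.DataFrame:
    """Three-way regulation labels for a knockout/knockdown study design.

    Presets
    -------
    ``fly``
        Requires metadata columns ``genotype`` (mutant/control), ``sex``
        and ``stage`` (adult/larval).  Dependent: ΔPSI ≤ −20 with each
        sex ≤ −15 at either stage, or each sex ≤ −10 with mutant PSI ≤ 1.
        Sensitive: each sex ≤ −10 at either stage, or (when ``oe_dpsi``
        from an SRRM4 overexpression experiment is supplied) OE ΔPSI ≥ 15.
    ``mouse``
        Requires ``dataset`` (n2a / hippocampus / cortex) and ``genotype``.
        Dependent: in any dataset, ΔPSI ≤ −20 with range gap ≥ 15, or
        ΔPSI ≤ −10 with maximum mutant PSI ≤ 1.  Sensitive: N2A ΔPSI
        ≤ −15 with range gap ≥ 5, or ΔPSI ≤ −10 in both hippocampus and
        cortex.
    ``human_oe``
        Requires ``genotype`` (overexpression coded as the ``mutant``
        value) and ``replicate``.  Enhanced (labelled dependent): ΔPSI
        ≥ 40 with replicate-wise ΔPSI within 10 of each other.

    Covered-but-unregulated events are eMIC-independent; events without an
    evaluable comparison are no-coverage.  Precedence: dependent >
    sensitive > independent.
    """
    meta = matrix.metadata
    events = matrix.psi.index
    label = pd.Series(LABEL_NO_COVERAGE, index=events, dtype=object)
    branch = pd.Series("", index=events, dtype=object)
    evidence: dict[str, pd.Series] = {}

    if preset == "fly":
        sexes = sorted(meta["sex"].unique())
        stages = sorted(meta["stage"].unique())
        dep = pd.Series(False, index=events)
        dep_low = pd.Series(False, index=events)
        sens = pd.Series(False, index=events)
        covered = pd.Series(False, index=events)
        for stage in stages:
            t = _group_cols(matrix, genotype=mutant, stage=stage)
            r = _group_cols(matrix, genotype=control, stage=stage)
            if not t or not r:
                raise ValueError(f"fly preset needs {mutant} and {control} samples at stage {stage}")
            dp = _comparison(matrix, t, r, sexes, "sex", meta)
            sex_cols = [f"dpsi_{s}" for s in sexes]
            ok = dp[sex_cols].notna().all(axis=1)
            covered |= ok
            all_sex = lambda thr: ok & pd.concat(
                [dp[c] <= thr for c in sex_cols], axis=1).all(axis=1)
            dep |= (dp["dpsi"] <= -dpsi_thresh) & all_sex(-sex_thresh)
            dep_low |= all_sex(-sensitive_thresh) & (dp["max_test"] <= low_psi)
            sens |= all_sex(-sensitive_thresh)
            evidence[f"dpsi_{stage}"] = dp["dpsi"]
            for s in sexes:
                evidence[f"dpsi_{stage}_{s}"] = dp[f"dpsi_{s}"]
        sens_oe = pd.Series(False, index=events)
        if oe_dpsi is not None:
            sens_oe = oe_dpsi.reindex(events) >= oe_thresh
            sens_oe = sens_oe.fillna(False)
            evidence["dpsi_srrm4_oe"] = oe_dpsi.reindex(events)
        label[covered] = LABEL_INDEPENDENT
        branch[covered] = "covered"
        take = (sens & covered) | sens_oe
        label[take] = LABEL_SENSITIVE
        branch[sens_oe & ~(dep | dep_low)] = "srrm4-oe"
        branch[sens & covered & ~(dep | dep_low)] = "dpsi10-both-sexes"
        label[dep_low & covered] = LABEL_DEPENDENT
        branch[dep_low & covered] = "low-inclusion"
        label[dep & covered] = LABEL_DEPENDENT
        branch[dep & covered] = "dpsi20-sex15"

    elif preset == "mouse":
        datasets = sorted(meta["dataset"].unique())
        stats = {}
        covered = pd.Series(False, index=events)
        for ds in datasets:
            t = _group_cols(matrix, genotype=mutant, dataset=ds)
            r = _group_cols(matrix, genotype=control, dataset=ds)
            if not t or not r:
                raise ValueError(f"mouse preset needs {mutant} and {control} samples in dataset {ds}")
            dp = delta_psi(matrix, t, r)
            stats[ds] = dp
            covered |= (dp["n_test"] >= 1) & (dp["n_ref"] >= 1)
            evidence[f"dpsi_{ds}"] = dp["dpsi"]
        dep = pd.Series(False, index=events)
        dep_low = pd.Series(False, index=events)
        for ds, dp in stats.items():
            dep |= (dp["dpsi"] <= -dpsi_thresh) & (dp["range_gap_down"] >= sex_thresh)
            dep_low |= (dp["dpsi"] <= -sensitive_thresh) & (dp["max_test"] <= low_psi)
        dep, dep_low = dep.fillna(False), dep_low.fillna(False)
        sens = pd.Series(False, index=events)
        if "n2a" in stats:
            dp = stats["n2a"]
            sens |= ((dp["dpsi"] <= -15) & (dp["range_gap_down"] >= 5)).fillna(False)
        if "hippocampus" in stats and "cortex" in stats:
            sens |= (
                (stats["hippocampus"]["dpsi"] <= -sensitive_thresh)
                & (stats["cortex"]["dpsi"] <= -sensitive_thresh)
            ).fillna(False)
        label[covered] = LABEL_INDEPENDENT
        branch[covered] = "covered"
        label[sens & covered] = LABEL_SENSITIVE
        branch[sens & covered] = "sensitive"
        label[dep_low & covered] = LABEL_DEPENDENT
        branch[dep_low & covered] = "low-inclusion"
        label[dep & covered] = LABEL_DEPENDENT
        branch[dep & covered] = "dpsi20-range15"

    elif preset == "human_oe":
        reps = sorted(meta["replicate"].unique())
        t_all = _group_cols(matrix, genotype=mutant)
        r_all = _group_cols(matrix, genotype=control)
        if not t_all or not r_all:
            raise ValueError("human_oe preset needs overexpression and control samples")
        dp = delta_psi(matrix, t_all, r_all)
        covered = (dp["n_test"] >= 1) & (dp["n_ref"] >= 1)
        rep_dpsi = []
        for rep in reps:
            t = [c for c in t_all if meta.at[c, "replicate"] == rep]
            r = [c for c in r_all if meta.at[c, "replicate"] == rep]
            if t and r:
                d = matrix.psi[t].mean(axis=1) - matrix.psi[r].mean(axis=1)
                rep_dpsi.append(d)
                evidence[f"dpsi_rep{rep}"] = d
        if len(rep_dpsi) >= 2:
            repmat = pd.concat(rep_dpsi, axis=1)
            rep_ok = (repmat.max(axis=1) - repmat.min(axis=1)) <= 10
            rep_ok &= repmat.notna().all(axis=1)
        else:
            rep_ok = pd.Series(True, index=events)
        enhanced = (dp["dpsi"] >= 40) & rep_ok
        evidence["dpsi_oe"] = dp["dpsi"]
        label[covered] = LABEL_INDEPENDENT
        branch[covered] = "covered"
        label[enhanced.fillna(False) & covered] = LABEL_DEPENDENT
        branch[enhanced.fillna(False) & covered] = "oe40-rep10"

    else:
        raise ValueError(f"unknown preset {preset!r}")

    res = pd.DataFrame({"label": label, "branch": branch})
    for k, v in evidence.items():
        res[k] = v
    return res


def call_sex_differential(
    matrix: PsiMatrix,
    mutant: str = "mutant",
    control: str = "control",
    stage: str | None = "adult",
    effect_thresh: float = 20.0,
    sex_diff_thresh: float = 20.0,
) -> pd.DataFrame:
    """Events with a sex-dependent response to the knockout.

    Requires both (a) |ΔPSI(mutant − control)| ≥ 20 in at least one sex
    and (b) |ΔPSI(male − female)| ≥ 20 within the control or the mutant
    genotype; reports which genotype(s) carry the sex difference.
    """
    meta = matrix.metadata
    if "sex" not in meta.columns:
        raise ValueError("sample metadata lacks a 'sex' column")
    crit = {} if stage is None else {"stage": stage}
    sexes = sorted(meta["sex"].unique())
    if len(sexes) != 2:
        raise ValueError("sex-differential calling needs exactly two sexes")
    ko_effect = {}
    for sex in sexes:
        t = matrix.samples_where(genotype=mutant, sex=sex, **crit)
        r = matrix.samples_where(genotype=control, sex=sex, **crit)
        if not t or not r:
            raise ValueError(f"missing samples for sex {sex}")
        ko_effect[sex] = matrix.psi[t].mean(axis=1) - matrix.psi[r].mean(axis=1)
    cond1 = pd.concat(
        [e.abs() >= effect_thresh for e in ko_effect.values()], axis=1
    ).any(axis=1)
    sexdiff = {}
    for geno in (control, mutant):
        a = matrix.samples_where(genotype=geno, sex=sexes[0], **crit)
        b = matrix.samples_where(genotype=geno, sex=sexes[1], **crit)
        sexdiff[geno] = matrix.psi[a].mean(axis=1) - matrix.psi[b].mean(axis=1)
    res = pd.DataFrame(index=matrix.psi.index)
    for sex, e in ko_effect.items():
        res[f"ko_dpsi_{sex}"] = e
    genos = []
    cond2 = pd.Series(False, index=res.index)
    for geno, d in sexdiff.items():
        hit = (d.abs() >= sex_diff_thresh).fillna(False)
        cond2 |= hit
        genos.append(pd.Series(np.where(hit, geno, ""), index=res.index))
        res[f"sex_dpsi_{geno}"] = d
    res["sex_differential"] = cond1.fillna(False) & cond2
    res["sexdiff_genotype"] = (genos[0] + "," + genos[1]).str.strip(",")
    res.loc[~res["sex_differential"], "sexdiff_genotype"] = ""
    return res


# ---------------------------------------------------------------------------
# control sets
# ---------------------------------------------------------------------------

@dataclass
class ControlSets:
    """Four disjoint comparison exon sets for cis-regulatory analyses."""

    high_psi: list[str]
    low_psi: list[str]
    neural: list[str]
    ase: list[str]
    seed: int = 0

    def as_dict(self) -> dict[str, list[str]]:
        return {
            "HighPSI": self.high_psi,
            "LowPSI": self.low_psi,
            "Neural": self.neural,
            "ASE": self.ase,
        }


def define_control_sets(
    matrix: PsiMatrix,
    tissue_col: str = "tissue_group",
    highpsi_cap: int = 1000,
    seed: int = 0,
    neural_events: Sequence[str] = (),
    exclude: Sequence[str] = (),
) -> ControlSets:
    """Define HighPSI / LowPSI / Neural / ASE control exon sets.

    HighPSI: per-tissue mean PSI > 90 in every covered tissue (down-sampled
    to ``highpsi_cap`` with ``seed``).  LowPSI: < 10 in every covered
    tissue.  ASE: 10 ≤ PSI ≤ 90 in ≥ 25% of informative samples with
    coverage in ≥ 3 tissues.  Neural: the supplied neural-enriched events
    minus the regulated (``exclude``) ones.  Sets are made pairwise
    disjoint in the order listed and all exclude ``exclude``.
    """
    meta = matrix.metadata
    if tissue_col not in meta.columns:
        raise ValueError(f"metadata lacks {tissue_col!r}")
    tissues = sorted(meta[tissue_col].dropna().unique())
    per_tissue = {}
    cover = {}
    for t in tissues:
        cols = matrix.samples_where(**{tissue_col: t})
        per_tissue[t] = matrix.psi[cols].mean(axis=1)
        cover[t] = matrix.psi[cols].notna().any(axis=1)
    pt = pd.DataFrame(per_tissue)
    cv = pd.DataFrame(cover)
    n_cov = cv.sum(axis=1)
    if int(n_cov.max()) < 3:
        raise ValueError("fewer than 3 covered tissues in the dataset")
    masked = pt.where(cv)

    high = (masked.min(axis=1) > 90) & (n_cov >= 1)
    low = (masked.max(axis=1) < 10) & (n_cov >= 1)
    psi = matrix.psi
    frac_alt = ((psi >= 10) & (psi <= 90)).sum(axis=1) / psi.notna().sum(axis=1).clip(lower=1)
    ase = (frac_alt >= 0.25) & (n_cov >= 3) & (psi.notna().sum(axis=1) > 0)

    excl = set(exclude)
    order = list(matrix.psi.index)
    high_ids = [e for e in order if high.get(e, False) and e not in excl]
    rng = np.random.default_rng(seed)
    if len(high_ids) > highpsi_cap:
        idx = rng.choice(len(high_ids), size=highpsi_cap, replace=False)
        high_ids = [high_ids[i] for i in sorted(idx)]
    taken = excl | set(high_ids)
    low_ids = [e for e in order if low.get(e, False) and e not in taken]
    taken |= set(low_ids)
    neural_ids = [e for e in order if e in set(neural_events) and e not in taken]
    taken |= set(neural_ids)
    ase_ids = [e for e in order if ase.get(e, False) and e not in taken]
    return ControlSets(high_ids, low_ids, neural_ids, ase_ids, seed)


# ---------------------------------------------------------------------------
# protein impact
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinImpact:
    event_id: str
    label: str  # ORF-preserving | frameshift | PTC-NMD | truncation | non-coding
    details: dict = field(default_factory=dict)


def _spliced_cds(tx: Transcript, seqs: SequenceStore) -> tuple[str, list[int]]:
    """CDS sequence (5'->3') and CDS-local positions of exon-exon junctions."""
    if tx.cds is None:
        raise ValueError(f"transcript {tx.transcript_id} has no CDS")
    lo, hi = tx.cds
    pieces, junctions, pos = [], [], 0
    exons = tx.exons  # genomic order
    for s, e in exons:
        a, b = max(s, lo), min(e, hi)
        if a < b:
            pieces.append(seqs.fetch(tx.chrom, a, b))
            pos += b - a
            junctions.append(pos)
    seq = "".join(pieces)
    junctions = junctions[:-1]  # last boundary is the CDS end, not a junction
    if tx.strand == "-":
        from .io_core import reverse_complement

        seq = reverse_complement(seq)
        junctions = [len(seq) - j for j in junctions][::-1]
    return seq, junctions


def _translate(seq: str) -> str:
    from Bio.Seq import Seq

    n = len(seq) - len(seq) % 3
    return str(Seq(seq[:n]).translate())


def classify_protein_impact(
    event: ExonEvent,
    annotation: GeneAnnotation,
    seqs: SequenceStore,
    nmd_distance: int = 50,
    max_truncation_aa: int = 300,
    max_truncation_frac: float = 0.2,
) -> ProteinImpact:
    """Predict the coding impact of including vs skipping the alt exon.

    Frameshift when the exon length is not a multiple of 3; otherwise both
    isoforms are translated and a premature stop triggers the canonical
    NMD rule (stop more than ``nmd_distance`` nt upstream of the last
    exon-exon junction) or the truncation rule (protein shortened by more
    than ``max_truncation_aa`` amino acids or ``max_truncation_frac`` of
    the reference isoform); else the exon is ORF-preserving.
    """
    inc_tx = skp_tx = None
    for tx in annotation.transcripts.values():
        if tx.gene_id != event.gene_id:
            continue
        ex = tx.exons
        for i in range(len(ex)):
            if ex[i] == event.alt and 0 < i < len(ex) - 1:
                inc_tx = tx
        for j in range(len(ex) - 1):
            pair = {ex[j], ex[j + 1]}
            if pair == {tuple(event.upstream), tuple(event.downstream)}:
                skp_tx = tx
    if inc_tx is None or skp_tx is None:
        raise ValueError(f"event {event.event_id} not resolvable in annotation")
    if inc_tx.cds is None or skp_tx.cds is None:
        return ProteinImpact(event.event_id, "non-coding", {"reason": "no CDS"})
    lo, hi = inc_tx.cds
    if event.alt[1] <= lo or event.alt[0] >= hi:
        return ProteinImpact(event.event_id, "non-coding", {"reason": "exon outside ORF"})

    if event.alt_length % 3 != 0:
        return ProteinImpact(
            event.event_id, "frameshift", {"alt_length": event.alt_length}
        )

    def first_stop(seq: str) -> int | None:
        prot = _translate(seq)
        k = prot.find("*")
        return None if k == -1 else k

    inc_seq, inc_junc = _spliced_cds(inc_tx, seqs)
    skp_seq, skp_junc = _spliced_cds(skp_tx, seqs)
    results = {}
    for name, (seq, junc) in {
        "inclusion": (inc_seq, inc_junc),
        "skipping": (skp_seq, skp_junc),
    }.items():
        k = first_stop(seq)
        terminal = k is not None and (k + 1) * 3 >= len(seq) - 2
        results[name] = {"stop_aa": k, "premature": k is not None and not terminal,
                         "seq": seq, "junctions": junc}
    # the disrupted isoform, if any, is compared against the intact one
    disrupted = [n for n, r in results.items() if r["premature"]]
    if not disrupted:
        return ProteinImpact(event.event_id, "ORF-preserving", {})
    name = disrupted[0]
    r = results[name]
    ref_name = "skipping" if name == "inclusion" else "inclusion"
    ref = results[ref_name]
    ref_len = ref["stop_aa"] if ref["stop_aa"] is not None else len(_translate(ref["seq"]))
    stop_end_nt = (r["stop_aa"] + 1) * 3
    last_junc = r["junctions"][-1] if r["junctions"] else 0
    details = {
        "isoform": name,
        "stop_aa": r["stop_aa"],
        "stop_to_last_junction_nt": last_junc - stop_end_nt,
        "reference_protein_aa": ref_len,
    }
    if last_junc - stop_end_nt > nmd_distance:
        return ProteinImpact(event.event_id, "PTC-NMD", details)
    lost = max(ref_len - r["stop_aa"], 0)
    details["lost_aa"] = lost
    details["lost_fraction"] = lost / ref_len if ref_len else 0.0
    if lost > max_truncation_aa or (ref_len and lost / ref_len > max_truncation_frac):
        return ProteinImpact(event.event_id, "truncation", details)
    return ProteinImpact(event.event_id, "ORF-preserving", details)


# ---------------------------------------------------------------------------
# RBP perturbation group-shift tests
# ---------------------------------------------------------------------------

def group_shift_test(
    emic_dpsi: Mapping[str, Sequence[float]],
    ase_dpsi: Mapping[str, Sequence[float]],
    min_n: int = 3,
) -> pd.DataFrame:
    """Per-perturbation Mann-Whitney U of eMIC-target ΔPSIs vs ASE ΔPSIs.

    BH correction is applied across perturbations; perturbations where
    either group has fewer than ``min_n`` finite values are skipped.
    """
    rows = []
    for pert in emic_dpsi:
        x = np.asarray(emic_dpsi[pert], dtype=float)
        y = np.asarray(ase_dpsi.get(pert, []), dtype=float)
        x, y = x[np.isfinite(x)], y[np.isfinite(y)]
        if x.size < min_n or y.size < min_n:
            continue
        u, p = mann_whitney_u(x, y, alternative="two-sided")
        rows.append(
            {"perturbation": pert, "n_emic": x.size, "n_ase": y.size,
             "median_shift": float(np.median(x) - np.median(y)), "U": u, "p": p}
        )
    res = pd.DataFrame(rows)
    if len(res):
        res["q"] = bh_fdr(res["p"].to_numpy())
    else:
        res["q"] = []
    return res
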