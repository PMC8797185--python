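"""Synthetic data with planted ground truth for every pipeline stage.

Generates a small genome of cassette-exon genes, a multi-panel PSI
matrix (knockout design, tissue atlas, neural cell types), junction
counts, chain files realising chosen conservation scenarios, a
conservation score track and ortholog protein pairs — all deterministic
under a single seed and all re-readable through :mod:`spliceprog.io_core`.

The generator's defaults mirror the statistical structure of the study
designs the package targets: regulated exons are short (median near
31 nt) with short flanking introns; knockout effects push their
inclusion towards zero; a branch-point-like CUAAY motif is planted
upstream of the regulated 3' splice sites at high occurrence versus a
low background in control exons; replicate noise is logit-normal with a
PSI-scale standard deviation of ~3 points at intermediate inclusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .conservation import ProteinWithExons
from .io_core import JunctionCountTable, PsiMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_annotation_and_sequences",
    "simulate_psi_dataset",
    "simulate_junction_counts",
    "simulate_chains",
    "simulate_conservation_track",
    "simulate_ortholog_pairs",
    "simulate_all",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic datasets."""

    seed: int = 0
    n_genes: int = 200
    # planted regulation classes
    n_dependent: int = 30
    n_low_branch: int = 4  # dependent via the low-inclusion branch (subset of n_dependent)
    n_sensitive: int = 20
    n_highpsi: int = 25
    n_lowpsi: int = 25
    n_ase: int = 40
    n_tissue_enriched: int = 30
    # design
    n_replicates_ko: int = 4  # per genotype x sex x stage
    n_replicates_tissue: int = 2
    noise_sd: float = 3.0  # PSI points at intermediate inclusion
    frac_vlow_quality: float = 0.05
    # sequence architecture
    flank_exon_range: tuple[int, int] = (120, 180)
    short_intron_range: tuple[int, int] = (60, 90)
    long_intron_range: tuple[int, int] = (200, 600)
    long_alt_range: tuple[int, int] = (84, 150)
    dep_alt_median: float = 31.0
    dep_alt_sigma: float = 0.35
    spacer: int = 100
    # motif planting
    motif: str = "CTAAY"
    motif_window: tuple[int, int] = (-30, -10)  # relative to alt-exon 3'ss, motif fully inside
    motif_prob_dependent: float = 0.9
    motif_prob_other: float = 0.1
    # junction usage at the three competing last-exon acceptors
    junction_usage: tuple[float, ...] = (0.1, 0.3, 0.6)
    junction_depth: int = 100_000
    # orthologs
    n_ortholog_pairs: int = 50
    ortholog_substitution_rate: float = 0.3
    ortholog_shared_fraction: float = 0.7

    def validate(self) -> None:
        n_special = (
            self.n_dependent + self.n_sensitive + self.n_highpsi
            + self.n_lowpsi + self.n_ase + self.n_tissue_enriched
        )
        if n_special > self.n_genes:
            raise ValueError("planted class counts exceed n_genes")
        if self.n_low_branch > self.n_dependent:
            raise ValueError("n_low_branch must not exceed n_dependent")
        if self.short_intron_range[0] < 40:
            raise ValueError("introns shorter than 40 nt cannot host the motif window")
        lo, hi = self.motif_window
        if hi - lo < len(self.motif):
            raise ValueError("motif window too narrow for the motif")


@dataclass
class GroundTruth:
    """Planted per-event truth sufficient to score every classifier."""

    events: pd.DataFrame  # indexed by event id
    true_psi: pd.DataFrame  # noise-free event x sample PSI
    sample_meta: pd.DataFrame
    junction_usage: dict[int, float]

    def event_ids(self, **criteria) -> list[str]:
        keep = pd.Series(True, index=self.events.index)
        for col, val in criteria.items():
            keep &= self.events[col] == val
        return list(self.events.index[keep])


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(_NT))[rng.integers(0, 4, size=n)])


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


def _noisy_psi(base: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Logit-normal noise calibrated to ~sd PSI points at mid inclusion.

    The logit-scale SD is sd / (100 * p(1-p)) with p(1-p) floored at 0.05,
    so values near the 0/100 boundaries stay near the boundary (as PSI
    estimates from finite read counts do).
    """
    p = np.clip(np.asarray(base, dtype=float) / 100.0, 1e-4, 1 - 1e-4)
    denom = np.maximum(p * (1 - p), 0.05)
    y = np.log(p / (1 - p)) + rng.standard_normal(p.shape) * sd / (100.0 * denom)
    return 100.0 / (1.0 + np.exp(-y))


# ---------------------------------------------------------------------------
# annotation + sequences
# ---------------------------------------------------------------------------

def _class_assignment(cfg: SimulationConfig) -> list[tuple[str, str]]:
    """(regulation_class, control_class) per gene index."""
    out = []
    for i in range(cfg.n_genes):
        if i < cfg.n_dependent:
            branch = "low" if i < cfg.n_low_branch else "main"
            out.append(("dependent", branch))
        elif i < cfg.n_dependent + cfg.n_sensitive:
            out.append(("sensitive", ""))
        elif i < cfg.n_dependent + cfg.n_sensitive + cfg.n_highpsi:
            out.append(("highpsi", ""))
        elif i < cfg.n_dependent + cfg.n_sensitive + cfg.n_highpsi + cfg.n_lowpsi:
            out.append(("lowpsi", ""))
        elif i < (cfg.n_dependent + cfg.n_sensitive + cfg.n_highpsi + cfg.n_lowpsi
                  + cfg.n_ase):
            out.append(("ase", ""))
        elif i < (cfg.n_dependent + cfg.n_sensitive + cfg.n_highpsi + cfg.n_lowpsi
                  + cfg.n_ase + cfg.n_tissue_enriched):
            out.append(("tissue", ""))
        else:
            out.append(("other", ""))
    return out


TISSUES = [
    ("brain", "neural"), ("ganglion", "neural"),
    ("eye", "sensory"), ("antenna", "sensory"),
    ("muscle", "muscle"), ("gut", "digestive"), ("salivary", "salivary"),
    ("ovary", "ovary"), ("testis", "testis"), ("accgland", "sexgland"),
]
TISSUE_GROUPS = ["neural", "sensory", "muscle", "digestive", "salivary",
                 "ovary", "testis", "sexgland"]
CELL_CLASSES = [("glia", 2), ("photoreceptor", 2), ("kenyon", 2),
                ("neuron_a", 3), ("neuron_b", 3)]


def simulate_annotation_and_sequences(cfg: SimulationConfig) -> tuple[str, str, pd.DataFrame]:
    """Build the synthetic genome: (gtf_text, fasta_text, event table).

    Each gene carries one cassette exon between two constitutive flanks,
    an including and a skipping transcript, GT..AG intron boundaries and
    class-dependent exon/intron length distributions; the branch-point
    motif is planted in the window upstream of the alt-exon 3' splice
    site with a class-dependent probability.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed).spawn(2)
    rng = np.random.default_rng(ss[0])
    classes = _class_assignment(cfg)
    chrom = "chr1"
    genome_parts: list[str] = []
    cursor = 0
    gtf_lines: list[str] = []
    rows = []
    from .cisreg import IUPAC

    motif_tmpl = cfg.motif.upper().replace("U", "T")
    dep_cons_cycle = [4, 4, 2]
    other_cons_cycle = [4, 1, 2, 3]
    dep_i = other_i = 0
    for gi, (reg, branch) in enumerate(classes):
        gene = f"g{gi:03d}"
        strand = "+" if gi % 2 == 0 else "-"
        e1 = int(rng.integers(*cfg.flank_exon_range))
        e2 = int(rng.integers(*cfg.flank_exon_range))
        if reg in ("dependent", "sensitive"):
            alt = int(np.clip(round(float(
                np.exp(np.log(cfg.dep_alt_median)
                       + cfg.dep_alt_sigma * rng.standard_normal()))), 6, 63))
            i1 = int(rng.integers(*cfg.short_intron_range))
            i2 = int(rng.integers(*cfg.short_intron_range))
        else:
            alt = int(rng.integers(*cfg.long_alt_range))
            i1 = int(rng.integers(*cfg.long_intron_range))
            i2 = int(rng.integers(*cfg.long_intron_range))
        if alt >= i1 or alt >= i2:
            # keep the skipping isoform's intron longer than the exon it removes
            i1, i2 = max(i1, alt + 20), max(i2, alt + 20)

        exon1 = _rand_seq(rng, e1)
        exon_alt = _rand_seq(rng, alt)
        exon2 = _rand_seq(rng, e2)
        intron1 = list("GT" + _rand_seq(rng, i1 - 4) + "AG")
        intron2 = list("GT" + _rand_seq(rng, i2 - 4) + "AG")
        p_mot = cfg.motif_prob_dependent if reg == "dependent" else cfg.motif_prob_other
        motif_pos = np.nan
        if rng.random() < p_mot:
            mot = "".join(
                IUPAC[ch][int(rng.integers(0, len(IUPAC[ch])))] for ch in motif_tmpl
            )
            lo, hi = cfg.motif_window
            start_rel = int(rng.integers(lo, hi - len(mot) + 2))  # fully inside window
            idx = i1 + start_rel  # position relative to alt exon start
            intron1[idx:idx + len(mot)] = list(mot)
            # planting must not clobber the terminal AG
            intron1[-2:], intron1[:2] = list("AG"), list("GT")
            motif_pos = start_rel
        sense = exon1 + "".join(intron1) + exon_alt + "".join(intron2) + exon2
        R = len(sense)
        g0 = cursor + cfg.spacer
        genome_parts.append(_rand_seq(rng, cfg.spacer))
        genome_parts.append(sense if strand == "+" else _revcomp(sense))
        cursor = g0 + R

        def g_iv(s0: int, s1: int) -> tuple[int, int]:
            if strand == "+":
                return (g0 + s0, g0 + s1)
            return (g0 + R - s1, g0 + R - s0)

        iv_e1 = g_iv(0, e1)
        iv_alt = g_iv(e1 + i1, e1 + i1 + alt)
        iv_e2 = g_iv(e1 + i1 + alt + i2, R)
        event_id = f"{gene}:{chrom}:{iv_alt[0]}-{iv_alt[1]}:{strand}"

        def feat(kind, iv, tx=None):
            attrs = f'gene_id "{gene}";'
            if tx:
                attrs += f' transcript_id "{tx}";'
            gtf_lines.append(
                f"{chrom}\tsim\t{kind}\t{iv[0] + 1}\t{iv[1]}\t.\t{strand}\t.\t{attrs}"
            )

        span = (g0, g0 + R)
        feat("gene", span)
        feat("transcript", span, f"{gene}.inc")
        for iv in sorted([iv_e1, iv_alt, iv_e2]):
            feat("exon", iv, f"{gene}.inc")
        feat("transcript", span, f"{gene}.skp")
        for iv in sorted([iv_e1, iv_e2]):
            feat("exon", iv, f"{gene}.skp")

        if reg == "dependent":
            level = dep_cons_cycle[dep_i % len(dep_cons_cycle)]
            dep_i += 1
        else:
            level = other_cons_cycle[other_i % len(other_cons_cycle)]
            other_i += 1
            if level == 3 and alt < 80:
                level = 4  # level 3 needs a long exon to keep the region mappable
        rows.append(
            {
                "event": event_id, "gene": gene, "chrom": chrom, "strand": strand,
                "regulation": reg if reg in ("dependent", "sensitive") else "independent",
                "branch": branch, "control_class": reg if reg in
                ("highpsi", "lowpsi", "ase", "tissue", "other") else "",
                "alt_start": iv_alt[0], "alt_end": iv_alt[1],
                "up_start": iv_e1[0], "up_end": iv_e1[1],
                "down_start": iv_e2[0], "down_end": iv_e2[1],
                "gene_start": g0, "gene_end": g0 + R,
                "alt_len": alt, "intron1": i1, "intron2": i2,
                "motif_pos": motif_pos,
                "conservation_level": level,
            }
        )
    genome_parts.append(_rand_seq(rng, cfg.spacer))
    genome = "".join(genome_parts)
    fasta_lines = [">chr1"]
    for i in range(0, len(genome), 80):
        fasta_lines.append(genome[i:i + 80])
    events = pd.DataFrame(rows).set_index("event")
    return "\n".join(gtf_lines) + "\n", "\n".join(fasta_lines) + "\n", events


# ---------------------------------------------------------------------------
# PSI dataset
# ---------------------------------------------------------------------------

def _sample_design(cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    for stage in ("adult", "larval"):
        for sex in ("f", "m"):
            for geno in ("control", "mutant"):
                for r in range(cfg.n_replicates_ko):
                    rows.append(
                        dict(sample=f"ko_{stage}_{sex}_{geno}_{r}", dataset="emic_ko",
                             tissue="brain", tissue_group="neural", cell_class="",
                             genotype=geno, sex=sex, stage=stage)
                    )
    for tissue, group in TISSUES:
        for r in range(cfg.n_replicates_tissue):
            rows.append(
                dict(sample=f"t_{tissue}_{r}", dataset="tissue_atlas", tissue=tissue,
                     tissue_group=group, cell_class="", genotype="control",
                     sex="f" if r % 2 == 0 else "m", stage="adult")
            )
    for cls, n in CELL_CLASSES:
        for r in range(n):
            rows.append(
                dict(sample=f"c_{cls}_{r}", dataset="celltypes", tissue="brain",
                     tissue_group="neural", cell_class=cls, genotype="control",
                     sex="f", stage="adult")
            )
    return pd.DataFrame(rows).set_index("sample")


_DEP_TISSUE_CYCLE = ["neural"] * 22 + ["eye"] * 4 + ["shared"] * 4
_DEP_CELL_CYCLE = (["pan-neuronal"] * 18 + ["glia-shared"] * 3 + ["PR-up"] * 3
                   + ["KC-down"] * 3 + ["PR-down"] * 3)


def _true_profiles(cfg: SimulationConfig, events: pd.DataFrame,
                   rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Noise-free PSI per event x sample, plus per-event profile labels."""
    meta = _sample_design(cfg)
    dep_ids = [e for e in events.index if events.at[e, "regulation"] == "dependent"]
    tissue_profile = {}
    cell_profile = {}
    labels = pd.DataFrame(index=events.index,
                          columns=["emic_tissue_group", "emic_celltype_group",
                                   "enriched_group"], dtype=object)
    labels[:] = ""
    u = rng.uniform
    for k, e in enumerate(dep_ids):
        tg = _DEP_TISSUE_CYCLE[k % len(_DEP_TISSUE_CYCLE)]
        cg = _DEP_CELL_CYCLE[k % len(_DEP_CELL_CYCLE)]
        labels.at[e, "emic_tissue_group"] = tg
        labels.at[e, "emic_celltype_group"] = cg
    enr_cycle = TISSUE_GROUPS
    ti = 0
    true = pd.DataFrame(0.0, index=events.index, columns=list(meta.index))
    for e in events.index:
        reg = events.at[e, "regulation"]
        cls = events.at[e, "control_class"]
        branch = events.at[e, "branch"]
        tp = {t: u(2, 6) for t, _ in TISSUES}
        cp = {c: u(2, 6) for c, _ in CELL_CLASSES}
        if reg == "dependent":
            if branch == "low":
                wt, mut = u(15, 17), u(0.05, 0.15)
            else:
                wt, mut = u(85, 95), u(0.3, 0.8)
            tg = labels.at[e, "emic_tissue_group"]
            if tg == "neural":
                for t in ("brain", "ganglion", "eye", "antenna"):
                    tp[t] = wt
            elif tg == "eye":
                tp["eye"] = u(88, 92)
                tp["brain"] = tp["ganglion"] = u(55, 65)
            else:  # shared
                for t in ("brain", "ganglion", "eye", "antenna"):
                    tp[t] = wt
                tp["muscle"] = u(50, 60)
            cg = labels.at[e, "emic_celltype_group"]
            if cg == "glia-shared":
                cp.update(glia=u(60, 70), photoreceptor=wt, kenyon=wt,
                          neuron_a=wt, neuron_b=wt)
            elif cg == "PR-up":
                cp.update(photoreceptor=u(90, 95), kenyon=u(55, 65),
                          neuron_a=u(55, 65), neuron_b=u(55, 65))
            elif cg == "KC-down":
                cp.update(photoreceptor=u(68, 72), kenyon=u(13, 17),
                          neuron_a=u(83, 87), neuron_b=u(83, 87))
            elif cg == "PR-down":
                cp.update(photoreceptor=u(13, 17), kenyon=u(78, 82),
                          neuron_a=u(78, 82), neuron_b=u(78, 82))
            else:
                cp.update(photoreceptor=u(80, 90), kenyon=u(80, 90),
                          neuron_a=u(80, 90), neuron_b=u(80, 90))
        elif reg == "sensitive":
            wt = u(45, 65)
            mut = wt - 15.0
            for t in ("brain", "ganglion", "eye", "antenna"):
                tp[t] = wt
            cp.update(photoreceptor=wt, kenyon=wt, neuron_a=wt, neuron_b=wt)
        else:
            if cls == "highpsi":
                base = u(97, 99)
            elif cls == "lowpsi":
                base = u(1, 3)
            elif cls == "ase":
                base = u(45, 55)
            elif cls == "tissue":
                base = u(18, 22)
            else:
                base = u(20, 80)
            wt = mut = base
            tp = {t: base for t, _ in TISSUES}
            cp = {c: base for c, _ in CELL_CLASSES}
            if cls == "tissue":
                grp = enr_cycle[ti % len(enr_cycle)]
                ti += 1
                labels.at[e, "enriched_group"] = grp
                hi = u(55, 65)
                for t, g in TISSUES:
                    if g == grp:
                        tp[t] = hi
        for s in meta.index:
            ds = meta.at[s, "dataset"]
            if ds == "emic_ko":
                v = mut if meta.at[s, "genotype"] == "mutant" else wt
                if events.at[e, "regulation"] == "independent":
                    v = tp["brain"]
            elif ds == "tissue_atlas":
                v = tp[meta.at[s, "tissue"]]
            else:
                v = cp[meta.at[s, "cell_class"]]
            true.at[e, s] = v
    return true, labels


def simulate_psi_dataset(cfg: SimulationConfig, events: pd.DataFrame) -> tuple[PsiMatrix, GroundTruth]:
    """Noisy PSI matrix over the three sample panels, plus ground truth.

    Zero-noise configurations reproduce the planted effects exactly; a
    configurable fraction of cells is downgraded to VLOW quality to
    exercise coverage masking.
    """
    ss = np.random.SeedSequence(cfg.seed).spawn(4)
    rng_true = np.random.default_rng(ss[1])
    rng_noise = np.random.default_rng(ss[2])
    rng_q = np.random.default_rng(ss[3])
    true, labels = _true_profiles(cfg, events, rng_true)
    meta = _sample_design(cfg)
    noisy = _noisy_psi(true.to_numpy(), cfg.noise_sd, rng_noise) if cfg.noise_sd > 0 \
        else true.to_numpy().copy()
    psi = pd.DataFrame(noisy, index=true.index, columns=true.columns)
    qvals = np.where(rng_q.random(psi.shape) < cfg.frac_vlow_quality, "VLOW", "OK")
    qvals = np.where((qvals == "OK") & (rng_q.random(psi.shape) < 0.1), "SOK", qvals)
    quality = pd.DataFrame(qvals, index=psi.index, columns=psi.columns)
    info = pd.DataFrame(
        {
            "GENE": events["gene"],
            "COORD": [f"{events.at[e, 'chrom']}:{events.at[e, 'alt_start']}-"
                      f"{events.at[e, 'alt_end']}" for e in events.index],
            "LENGTH": events["alt_len"],
        },
        index=events.index,
    )
    matrix = PsiMatrix(psi, quality, meta, info)
    ev = events.copy()
    for c in labels.columns:
        ev[c] = labels[c]
    truth = GroundTruth(ev, true, meta,
                        dict(zip((21, 22, 23), cfg.junction_usage)))
    return matrix, truth


# ---------------------------------------------------------------------------
# junctions, chains, track, orthologs
# ---------------------------------------------------------------------------

def simulate_junction_counts(
    usage: Sequence[float],
    depth: int,
    seed: int,
    gene: str = "Srrm234",
    donor: int = 20,
    acceptors: Sequence[int] = (21, 22, 23),
) -> JunctionCountTable:
    """Multinomial junction reads from one shared donor across acceptors."""
    usage = np.asarray(usage, dtype=float)
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not math.isclose(usage.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("usage must sum to 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth, usage)
    recs = [(gene, donor, a, int(c)) for a, c in zip(acceptors, counts)]
    return JunctionCountTable.from_records(recs)


def simulate_chains(events: pd.DataFrame, target_prefix: str = "chrB") -> str:
    """Chain file realising each event's planted conservation level.

    Level 4: identity chain over the gene region; level 3: both boundary
    dinucleotides fall in 4-nt gaps while >=95% of the exon stays
    aligned; level 2: the alt exon is deleted from the target; level 1:
    no chain covers the locus.
    """
    lines = []
    q_cursor = 0
    chain_id = 1
    t_size = int(events["gene_end"].max()) + 1000
    for e in events.index:
        level = int(events.at[e, "conservation_level"])
        if level == 1:
            continue
        g0, g1 = int(events.at[e, "gene_start"]), int(events.at[e, "gene_end"])
        a0, a1 = int(events.at[e, "alt_start"]), int(events.at[e, "alt_end"])
        chrom = events.at[e, "chrom"]
        if level == 4:
            blocks = [(g1 - g0, None)]
        elif level == 2:
            blocks = [(a0 - g0, (a1 - a0, 0)), (g1 - a1, None)]
        else:  # level 3: 4-nt gaps centred on both exon boundaries
            blocks = [
                (a0 - 2 - g0, (4, 4)),
                ((a1 - 2) - (a0 + 2), (4, 4)),
                (g1 - (a1 + 2), None),
            ]
        q_len = sum(size for size, _ in blocks) + sum(
            gap[1] for _, gap in blocks if gap is not None
        )
        q_name = f"{target_prefix}1"
        lines.append(
            f"chain 1000 {chrom} {t_size} + {g0} {g1} {q_name} 10000000 + "
            f"{q_cursor} {q_cursor + q_len} {chain_id}"
        )
        for size, gap in blocks:
            if gap is None:
                lines.append(f"{size}")
            else:
                lines.append(f"{size} {gap[0]} {gap[1]}")
        lines.append("")
        q_cursor += q_len + 100
        chain_id += 1
    return "\n".join(lines) + "\n"


def simulate_conservation_track(events: pd.DataFrame, seed: int) -> str:
    """bedGraph with high scores over exons and low scores over introns."""
    rng = np.random.default_rng(seed)
    lines = []
    for e in events.index:
        chrom = events.at[e, "chrom"]
        ivs = sorted(
            [
                (int(events.at[e, "up_start"]), int(events.at[e, "up_end"]), "exon"),
                (int(events.at[e, "alt_start"]), int(events.at[e, "alt_end"]), "exon"),
                (int(events.at[e, "down_start"]), int(events.at[e, "down_end"]), "exon"),
            ]
        )
        g0, g1 = int(events.at[e, "gene_start"]), int(events.at[e, "gene_end"])
        cursor = g0
        for s, t, kind in ivs:
            if cursor < s:
                lines.append(f"{chrom}\t{cursor}\t{s}\t{round(0.2 + 0.05 * rng.random(), 3)}")
            lines.append(f"{chrom}\t{s}\t{t}\t{round(0.85 + 0.1 * rng.random(), 3)}")
            cursor = t
        if cursor < g1:
            lines.append(f"{chrom}\t{cursor}\t{g1}\t{round(0.2 + 0.05 * rng.random(), 3)}")
    return "\n".join(lines) + "\n"


def simulate_ortholog_pairs(
    n_pairs: int,
    substitution_rate: float,
    seed: int,
    shared_fraction: float = 0.7,
    alt_exon_aa: int = 10,
) -> list[tuple[ProteinWithExons, ProteinWithExons, bool]]:
    """Ortholog protein pairs with the alt exon shared or in a different intron.

    The partner protein is derived by per-residue point substitutions at
    ``substitution_rate``; shared exons sit between the same flanking
    exons in both species, unshared ones are inserted one intron
    downstream in the partner.
    """
    if not 0 <= substitution_rate <= 0.5:
        raise ValueError("substitution rate must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    out = []
    aa = np.array(list(_AA))

    def substitute(seq: str) -> str:
        s = list(seq)
        for i in range(len(s)):
            if rng.random() < substitution_rate:
                choices = [c for c in _AA if c != s[i]]
                s[i] = choices[int(rng.integers(0, len(choices)))]
        return "".join(s)

    for k in range(n_pairs):
        shared = k < int(round(n_pairs * shared_fraction))
        lens = [int(rng.integers(30, 50)), int(rng.integers(25, 40)),
                alt_exon_aa, int(rng.integers(25, 40)), int(rng.integers(30, 50))]
        exon_seqs = ["".join(aa[rng.integers(0, 20, size=n)]) for n in lens]
        seq_a = "".join(exon_seqs)
        idx_a = [i for i, s in enumerate(exon_seqs) for _ in s]
        prot_a = ProteinWithExons(f"A{k}", seq_a, idx_a)
        sub = [substitute(s) for s in exon_seqs]
        alt_b = "".join(aa[rng.integers(0, 20, size=alt_exon_aa)])
        if shared:
            b_seqs = [sub[0], sub[1], sub[2], sub[3], sub[4]]
        else:
            # alt exon moved one intron downstream in the partner gene
            b_seqs = [sub[0], sub[1], sub[3], alt_b, sub[4]]
        seq_b = "".join(b_seqs)
        idx_b = [i for i, s in enumerate(b_seqs) for _ in s]
        prot_b = ProteinWithExons(f"B{k}", seq_b, idx_b)
        out.append((prot_a, prot_b, shared))
    return out


# ---------------------------------------------------------------------------
# one-call emission
# ---------------------------------------------------------------------------

def simulate_all(cfg: SimulationConfig, outdir) -> dict:
    """Emit every synthetic input file into ``outdir``; fully seed-determined.

    Writes genome.fa, annotation.gtf, psi.tsv, samples.tsv,
    junctions.tsv, liftover.chain, conservation.bedgraph and
    truth_events.tsv, and returns the paths together with the in-memory
    matrix and ground truth.
    """
    from .io_core import write_psi_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gtf, fasta, events = simulate_annotation_and_sequences(cfg)
    matrix, truth = simulate_psi_dataset(cfg, events)
    junc = simulate_junction_counts(cfg.junction_usage, cfg.junction_depth,
                                    int(np.random.SeedSequence(cfg.seed).spawn(5)[4]
                                        .generate_state(1)[0] % (2 ** 31)))
    chain_text = simulate_chains(truth.events)
    track_text = simulate_conservation_track(truth.events, cfg.seed + 17)
    paths = {
        "gtf": outdir / "annotation.gtf",
        "fasta": outdir / "genome.fa",
        "psi": outdir / "psi.tsv",
        "samples": outdir / "samples.tsv",
        "junctions": outdir / "junctions.tsv",
        "chain": outdir / "liftover.chain",
        "bedgraph": outdir / "conservation.bedgraph",
        "truth": outdir / "truth_events.tsv",
    }
    paths["gtf"].write_text(gtf)
    paths["fasta"].write_text(fasta)
    write_psi_table(matrix, paths["psi"])
    meta = truth.sample_meta.reset_index()
    meta.to_csv(paths["samples"], sep="\t", index=False)
    with open(paths["junctions"], "w") as fh:
        fh.write("gene\tdonor\tacceptor\tcount\n")
        for (g, d, a), c in sorted(junc.counts.items()):
            fh.write(f"{g}\t{d}\t{a}\t{c}\n")
    paths["chain"].write_text(chain_text)
    paths["bedgraph"].write_text(track_text)
    truth.events.to_csv(paths["truth"], sep="\t")
    return {"paths": paths, "matrix": matrix, "truth": truth, "config": cfg}
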