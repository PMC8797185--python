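"""Cross-species exon conservation and orthology.

A minimal, single-chain re-implementation of chain-based interval
lifting (UCSC chain format, colinear blocks, default minimum match
fraction 0.95) drives a four-level conservation classification of
cassette exons:

1. region unmappable (flanking exons included),
2. flanking exons map but the alternative exon region does not,
3. the exon region maps but neither splice site is present,
4. at least one splice-site boundary dinucleotide maps (conserved).

Conservation-score meta-profiles average a per-base track around exon
starts and ends, masking nearby flanking exons, the first 10 nt of the
upstream intron and the last 30 nt of the downstream intron.

Exon orthology between proteins of orthologous genes uses a global
protein alignment (BLOSUM62, gap open 10 / extend 1) and calls two exons
orthologous when they lie in the same intron, i.e. their upstream and
downstream flanking exons mutually overlap at least half of their
aligned columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_core import ExonEvent, ScoreTrack

__all__ = [
    "Chain",
    "ChainSet",
    "read_chain_file",
    "map_interval",
    "ConservationCall",
    "classify_exon_conservation",
    "MetaProfile",
    "conservation_metaprofile",
    "ProteinWithExons",
    "ExonOrthologyCall",
    "align_proteins",
    "alignment_score",
    "align_and_match_exons",
]


# ---------------------------------------------------------------------------
# chains and lifting
# ---------------------------------------------------------------------------

@dataclass
class Chain:
    score: float
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    blocks: list[tuple[int, int, int]]  # (t_start, q_start_strandcoords, size)

    def map_position(self, t: int) -> int | None:
        """Map a source position to forward-strand target coordinates."""
        for ts, qs, size in self.blocks:
            if ts <= t < ts + size:
                q = qs + (t - ts)
                if self.q_strand == "-":
                    return self.q_size - 1 - q
                return q
        return None

    def covered(self, start: int, end: int) -> int:
        return sum(
            max(0, min(end, ts + size) - max(start, ts))
            for ts, qs, size in self.blocks
        )


@dataclass
class ChainSet:
    chains: list[Chain] = field(default_factory=list)

    def for_interval(self, chrom: str, start: int, end: int) -> list[Chain]:
        hits = [
            c for c in self.chains
            if c.t_name == chrom and c.t_start < end and c.t_end > start
        ]
        return sorted(hits, key=lambda c: -c.score)


def read_chain_file(path) -> ChainSet:
    """Parse a UCSC chain file (header line + ungapped block lines)."""
    chains: list[Chain] = []
    with open(path) as fh:
        header = None
        blocks: list[tuple[int, int, int]] = []
        t_pos = q_pos = 0
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("chain"):
                f = line.split()
                header = Chain(
                    score=float(f[1]), t_name=f[2], t_size=int(f[3]),
                    t_start=int(f[5]), t_end=int(f[6]),
                    q_name=f[7], q_size=int(f[8]), q_strand=f[9],
                    q_start=int(f[10]), q_end=int(f[11]), blocks=[],
                )
                if f[4] != "+":
                    raise ValueError("chain tStrand must be '+'")
                t_pos, q_pos = header.t_start, header.q_start
                blocks = []
                continue
            f = line.split()
            size = int(f[0])
            blocks.append((t_pos, q_pos, size))
            if len(f) == 3:
                t_pos += size + int(f[1])
                q_pos += size + int(f[2])
            else:
                header.blocks = blocks
                chains.append(header)
                header = None
    return ChainSet(chains)


@dataclass(frozen=True)
class MappedInterval:
    chrom: str
    start: int
    end: int
    strand: str
    match_fraction: float


def map_interval(
    chains: ChainSet,
    chrom: str,
    start: int,
    end: int,
    min_match: float = 0.95,
) -> MappedInterval | None:
    """Lift a source interval through the best-scoring covering chain.

    Succeeds when at least ``min_match`` of the interval's bases fall in
    aligned blocks of a single chain; the image is the colinear span of
    the mapped bases on the target (forward-strand coordinates).  Returns
    ``None`` when unmapped.
    """
    if end <= start:
        raise ValueError("empty interval")
    for chain in chains.for_interval(chrom, start, end):
        covered = chain.covered(start, end)
        frac = covered / (end - start)
        if frac < min_match or covered == 0:
            continue
        qpos = []
        for ts, qs, size in chain.blocks:
            a, b = max(start, ts), min(end, ts + size)
            if a < b:
                qpos.append(chain.map_position(a))
                qpos.append(chain.map_position(b - 1))
        qpos = [q for q in qpos if q is not None]
        if not qpos:
            continue
        return MappedInterval(
            chain.q_name, min(qpos), max(qpos) + 1,
            chain.q_strand, frac,
        )
    return None


# ---------------------------------------------------------------------------
# conservation levels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConservationCall:
    event_id: str
    target: str
    level: int  # 1..4
    conserved: bool
    details: dict

    def __post_init__(self) -> None:
        if self.level not in (1, 2, 3, 4):
            raise ValueError("level must be 1..4")


def _splice_site_intervals(event: ExonEvent) -> dict[str, tuple[int, int]]:
    """Genomic intervals of the boundary dinucleotides of the alt exon."""
    if event.strand == "+":
        return {
            "acceptor": (event.alt[0] - 2, event.alt[0]),
            "donor": (event.alt[1], event.alt[1] + 2),
        }
    return {
        "acceptor": (event.alt[1], event.alt[1] + 2),
        "donor": (event.alt[0] - 2, event.alt[0]),
    }


def classify_exon_conservation(
    event: ExonEvent,
    chains: ChainSet,
    min_match: float = 0.95,
    target: str = "",
    require_both_flanks: bool = True,
) -> ConservationCall:
    """Apply the four-level lift-based conservation decision tree.

    Splice-site presence is operationalised as full mappability of the
    2-nt boundary dinucleotide.
    """
    up = map_interval(chains, event.chrom, *event.upstream, min_match=min_match)
    down = map_interval(chains, event.chrom, *event.downstream, min_match=min_match)
    flanks_map = (up is not None and down is not None) if require_both_flanks else (
        up is not None or down is not None
    )
    details: dict = {"upstream_flank": up, "downstream_flank": down}
    if not flanks_map:
        return ConservationCall(event.event_id, target, 1, False, details)
    alt = map_interval(chains, event.chrom, *event.alt, min_match=min_match)
    details["alt_region"] = alt
    if alt is None:
        return ConservationCall(event.event_id, target, 2, False, details)
    sites = _splice_site_intervals(event)
    present = {}
    for name, iv in sites.items():
        m = map_interval(chains, event.chrom, *iv, min_match=1.0)
        present[name] = m is not None
    details["splice_sites"] = present
    if any(present.values()):
        return ConservationCall(event.event_id, target, 4, True, details)
    return ConservationCall(event.event_id, target, 3, False, details)


# ---------------------------------------------------------------------------
# conservation meta-profiles
# ---------------------------------------------------------------------------

@dataclass
class MetaProfile:
    """Mean track score aligned on exon starts and ends (sense orientation)."""

    positions: np.ndarray  # relative positions, same grid for both profiles
    mean_start: np.ndarray
    n_start: np.ndarray
    mean_end: np.ndarray
    n_end: np.ndarray
    flank: int
    masking: str = "flank-exons<flank; upstream intron first 10 nt; downstream intron last 30 nt"


def _event_positions(event: ExonEvent, anchor: str, flank: int) -> np.ndarray:
    """Genomic coordinates for sense-relative positions [-flank, flank)."""
    p = np.arange(-flank, flank)
    if anchor == "start":
        if event.strand == "+":
            return event.alt[0] + p
        return event.alt[1] - 1 - p
    if event.strand == "+":
        return event.alt[1] - 1 + p + 1  # position 0 = first intronic base after exon end
    return event.alt[0] - p - 1


def _mask(event: ExonEvent, anchor: str, flank: int,
          up_intron_mask: int, down_intron_mask: int) -> np.ndarray:
    """True where a relative position must be excluded for this event."""
    p = np.arange(-flank, flank)
    up_i = event.upstream_intron[1] - event.upstream_intron[0]
    dn_i = event.downstream_intron[1] - event.downstream_intron[0]
    alt = event.alt_length
    m = np.zeros_like(p, dtype=bool)
    if anchor == "start":
        intron_pos = -p  # distance into upstream intron for p < 0
        m |= (p < 0) & (intron_pos > up_i)  # inside/beyond upstream exon
        m |= (p < 0) & (intron_pos > up_i - up_intron_mask)  # first 10 nt of up intron
        m |= (p >= alt + dn_i)  # downstream exon
        m |= (p >= alt + dn_i - down_intron_mask) & (p >= alt)  # last 30 nt of down intron
    else:
        m |= (p >= 0) & (p >= dn_i)  # downstream exon
        m |= (p >= 0) & (p >= dn_i - down_intron_mask)  # last 30 nt of down intron
        m |= p < -(alt + up_i)  # upstream exon
        m |= (p < -alt) & (p < -(alt + up_i - up_intron_mask))  # first 10 nt of up intron
    return m


def conservation_metaprofile(
    track: ScoreTrack,
    events: Iterable[ExonEvent],
    flank: int = 150,
    up_intron_mask: int = 10,
    down_intron_mask: int = 30,
) -> MetaProfile:
    """Average per-base scores around exon starts and ends with masking.

    Masked positions contribute to neither the sum nor the count; events
    on contigs absent from the track are skipped.
    """
    n_pos = 2 * flank
    sums = {"start": np.zeros(n_pos), "end": np.zeros(n_pos)}
    counts = {"start": np.zeros(n_pos, dtype=np.int64), "end": np.zeros(n_pos, dtype=np.int64)}
    for ev in events:
        if ev.chrom not in track.chroms:
            continue
        for anchor in ("start", "end"):
            g = _event_positions(ev, anchor, flank)
            lo, hi = int(g.min()), int(g.max()) + 1
            vals = track.values(ev.chrom, lo, hi)
            v = vals[g - lo]
            mask = _mask(ev, anchor, flank, up_intron_mask, down_intron_mask)
            ok = np.isfinite(v) & ~mask
            sums[anchor][ok] += v[ok]
            counts[anchor][ok] += 1
    with np.errstate(invalid="ignore"):
        mean_start = np.where(counts["start"] > 0, sums["start"] / np.maximum(counts["start"], 1), np.nan)
        mean_end = np.where(counts["end"] > 0, sums["end"] / np.maximum(counts["end"], 1), np.nan)
    return MetaProfile(
        np.arange(-flank, flank), mean_start, counts["start"], mean_end, counts["end"], flank
    )


# ---------------------------------------------------------------------------
# exon orthology through protein alignment
# ---------------------------------------------------------------------------

@dataclass
class ProteinWithExons:
    """A protein sequence with, per residue, the index of its host exon."""

    name: str
    seq: str
    exon_index: Sequence[int]

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("empty protein sequence")
        if len(self.seq) != len(self.exon_index):
            raise ValueError("exon_index must have one entry per residue")

    @property
    def n_exons(self) -> int:
        return int(max(self.exon_index)) + 1


def _aligner():
    from Bio import Align
    from Bio.Align import substitution_matrices

    a = Align.PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -10.0
    a.extend_gap_score = -1.0
    return a


def alignment_score(seq_a: str, seq_b: str) -> float:
    return float(_aligner().score(seq_a, seq_b))


def align_proteins(seq_a: str, seq_b: str) -> list[tuple[int, int]]:
    """Residue index pairs of one optimal global alignment."""
    aln = _aligner().align(seq_a, seq_b)[0]
    pairs: list[tuple[int, int]] = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    return pairs


@dataclass(frozen=True)
class ExonOrthologyCall:
    gene_a: str
    gene_b: str
    exon_a: int
    exon_b: int | None
    status: str  # orthologous-exon | same-intron-exon-absent | no-match
    evidence: dict


def _mutual_overlap(pairs, exon_a_idx, exon_b_idx, ex_a: int, ex_b: int) -> tuple[float, float]:
    in_both = cols_a = cols_b = 0
    for i, j in pairs:
        a_in = exon_a_idx[i] == ex_a
        b_in = exon_b_idx[j] == ex_b
        cols_a += a_in
        cols_b += b_in
        in_both += a_in and b_in
    fa = in_both / cols_a if cols_a else 0.0
    fb = in_both / cols_b if cols_b else 0.0
    return fa, fb


def align_and_match_exons(
    prot_a: ProteinWithExons,
    prot_b: ProteinWithExons,
    alt_exon_a: int,
    overlap_thresh: float = 0.5,
) -> ExonOrthologyCall:
    """Match an exon of protein A to its orthologous exon in protein B.

    Exons are orthologous when the upstream flanking exons mutually
    overlap ≥ ``overlap_thresh`` of their aligned columns and likewise
    the downstream flanking exons (the "same intron" test); an exon
    matches at most one partner exon (best summed overlap wins).  When no
    exon matches but A's flanks align to two *adjacent* exons of B, the
    intron is conserved with the exon absent.
    """
    if alt_exon_a <= 0 or alt_exon_a >= prot_a.n_exons - 1:
        raise ValueError("alt exon must be internal (needs both flanks)")
    pairs = align_proteins(prot_a.seq, prot_b.seq)
    ia, ib = list(prot_a.exon_index), list(prot_b.exon_index)
    up_a, down_a = alt_exon_a - 1, alt_exon_a + 1
    best = None
    for b in range(1, prot_b.n_exons - 1):
        fu = _mutual_overlap(pairs, ia, ib, up_a, b - 1)
        fd = _mutual_overlap(pairs, ia, ib, down_a, b + 1)
        if min(fu) >= overlap_thresh and min(fd) >= overlap_thresh:
            score = sum(fu) + sum(fd)
            if best is None or score > best[1]:
                best = (b, score, fu, fd)
    if best is not None:
        b, score, fu, fd = best
        return ExonOrthologyCall(
            prot_a.name, prot_b.name, alt_exon_a, b, "orthologous-exon",
            {"upstream_overlap": fu, "downstream_overlap": fd},
        )
    for k in range(prot_b.n_exons - 1):
        fu = _mutual_overlap(pairs, ia, ib, up_a, k)
        fd = _mutual_overlap(pairs, ia, ib, down_a, k + 1)
        if min(fu) >= overlap_thresh and min(fd) >= overlap_thresh:
            return ExonOrthologyCall(
                prot_a.name, prot_b.name, alt_exon_a, None,
                "same-intron-exon-absent",
                {"upstream_overlap": fu, "downstream_overlap": fd},
            )
    return ExonOrthologyCall(prot_a.name, prot_b.name, alt_exon_a, None, "no-match", {})
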